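"""Ground-truth generator: motion statistics and rendering."""

import numpy as np
import pytest
from scipy import stats

from chromorheo import (
    AcquisitionConfig,
    MotionModel,
    ensemble_msd,
    make_fixture,
    render_stack,
    simulate_trajectories,
)
from chromorheo.constants import FWHM_SIGMA_FACTOR
from chromorheo.synthetic import ParticleOutOfBoundsError


def _free_config(**kw):
    defaults = dict(image_shape=(64, 64), duration_s=1.0, frame_rate_hz=512.0, seed=1)
    defaults.update(kw)
    return AcquisitionConfig(**defaults)


def _oracle_msd(positions, lag):
    """Independent step-summation MSD oracle: explicit double loop."""
    total, count = 0.0, 0
    for tr in positions:
        for j in range(len(tr) - lag):
            d = tr[j + lag] - tr[j]
            total += d @ d
            count += 1
    return total / count


class TestSimulateTrajectories:
    def test_zero_diffusion_is_static(self):
        cfg = _free_config()
        t = simulate_trajectories(
            1, MotionModel("free", 0.0), cfg, initial_positions_um=[[1.0, 2.0]]
        )
        assert np.all(t.positions_um == t.positions_um[:, :1, :])

    def test_free_msd_matches_4dt_and_oracle(self):
        D, cfg = 0.1, _free_config(seed=2)
        t = simulate_trajectories(
            200, MotionModel("free", D), cfg, initial_positions_um=np.zeros((200, 2))
        )
        curve = ensemble_msd(t.positions_um, cfg.dt_s, lags=np.arange(1, 11))
        # analytic: MSD_2D = 4 D tau within 3 SE at every lag <= 10 frames
        assert np.all(np.abs(curve.msd_um2 - 4 * D * curve.lag_s) < 3 * curve.se_um2)
        # short-lag ratio MSD/tau -> 4 D = 0.4 um^2/s
        assert curve.msd_um2[0] / curve.lag_s[0] == pytest.approx(0.4, rel=0.05)
        # cross-check the vectorized MSD against the explicit-loop oracle
        for lag in (1, 5):
            assert _oracle_msd(t.positions_um[:10], lag) == pytest.approx(
                ensemble_msd(t.positions_um[:10], cfg.dt_s, lags=[lag]).msd_um2[0]
            )

    def test_confined_msd_follows_analytic_ou(self):
        D, tau_r = 0.1, 0.05
        cfg = _free_config(seed=3, duration_s=4.0)
        t = simulate_trajectories(
            300,
            MotionModel("confined", D, relaxation_time_s=tau_r),
            cfg,
            initial_positions_um=np.zeros((300, 2)),
        )
        lags = np.array([1, 2, 5, 10, 26, 51, 128, 256, 512])
        curve = ensemble_msd(t.positions_um, cfg.dt_s, lags=lags)
        analytic = 4 * D * tau_r * (1 - np.exp(-curve.lag_s / tau_r))
        assert np.all(np.abs(curve.msd_um2 - analytic) < 4 * curve.se_um2)
        # long-lag plateau = 4 D tau_r
        assert curve.msd_um2[-1] == pytest.approx(4 * D * tau_r, rel=0.1)

    def test_drift_superlinear_and_removable(self):
        D, v = 0.01, (1.2, 0.8)
        cfg = _free_config(seed=4, duration_s=2.0)
        kw = dict(initial_positions_um=np.zeros((100, 2)))
        td = simulate_trajectories(
            100, MotionModel("drifting", D, drift_velocity_um_s=v), cfg, **kw
        )
        tf = simulate_trajectories(100, MotionModel("free", D), cfg, **kw)
        lags = np.array([1, 8, 64, 256])
        raw = ensemble_msd(td.positions_um, cfg.dt_s, lags=lags)
        # superlinear at long lags: log-log slope over the last decade > 1.5
        sl = np.diff(np.log(raw.msd_um2[-2:])) / np.diff(np.log(raw.lag_s[-2:]))
        assert sl[0] > 1.5
        # perfect drift subtraction using ground truth recovers free motion
        desub = td.positions_um - td.drift_um[None, :, :]
        assert np.allclose(desub, tf.positions_um)

    def test_free_increments_pass_normality(self):
        cfg = _free_config(seed=5)
        t = simulate_trajectories(
            100, MotionModel("free", 0.1), cfg, initial_positions_um=np.zeros((100, 2))
        )
        inc = np.diff(t.positions_um, axis=1).ravel()
        assert inc.size >= 1e5
        assert abs(stats.skew(inc)) < 0.1
        assert abs(stats.kurtosis(inc)) < 0.2

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            MotionModel("free", -0.1)
        with pytest.raises(ValueError):
            MotionModel("confined", 0.1)  # missing relaxation time
        with pytest.raises(ValueError):
            MotionModel("wiggly", 0.1)
        with pytest.raises(ValueError):
            AcquisitionConfig(frame_rate_hz=0.0)

    def test_reproducible_under_fixed_seed(self):
        cfg = _free_config(seed=6)
        a = simulate_trajectories(5, MotionModel("free", 0.05), cfg, init_margin_um=0.5)
        b = simulate_trajectories(5, MotionModel("free", 0.05), cfg, init_margin_um=0.5)
        assert np.array_equal(a.positions_um, b.positions_um)


class TestRenderStack:
    def test_single_particle_peak_at_its_pixel(self):
        cfg = _free_config(duration_s=1 / 512)
        t = simulate_trajectories(
            1,
            MotionModel("free", 0.0),
            cfg,
            initial_positions_um=[[1.5, 1.25]],  # pixel (col 30, row 25)
            diameters_um=[0.8],
        )
        img = render_stack(t, noise_sd=0.0)[0]
        assert np.unravel_index(img.argmax(), img.shape) == (25, 30)

    def test_rendered_sigma_follows_fwhm_identity(self):
        # diameter 1.0 um at 50 nm pixels -> sigma = 8.49 px
        cfg = _free_config(image_shape=(128, 128), duration_s=1 / 512)
        t = simulate_trajectories(
            1,
            MotionModel("free", 0.0),
            cfg,
            initial_positions_um=[[3.2, 3.2]],
            diameters_um=[1.0],
            peak_intensities=[100.0],
        )
        img = render_stack(t, background=0.0, noise_sd=0.0)[0]
        sigma_px = 1.0 / FWHM_SIGMA_FACTOR / 0.05
        assert sigma_px == pytest.approx(8.4932, abs=1e-3)
        # intensity profile along the row through the center
        row = img[64, :]
        xs = np.arange(128)
        half = row >= 50.0
        fwhm_measured = xs[half].max() - xs[half].min() + 1
        assert fwhm_measured == pytest.approx(1.0 / 0.05, abs=1.5)

    def test_integrated_intensity_matches_gaussian_integral(self):
        cfg = _free_config(image_shape=(200, 200), duration_s=1 / 512)
        diam = np.array([0.8, 1.2])
        peaks = np.array([300.0, 500.0])
        t = simulate_trajectories(
            2,
            MotionModel("free", 0.0),
            cfg,
            initial_positions_um=[[3.0, 3.0], [7.0, 7.0]],
            diameters_um=diam,
            peak_intensities=peaks,
        )
        img = render_stack(t, background=10.0, noise_sd=0.0)[0]
        total = img.sum() - 10.0 * img.size
        sigmas_px = diam / FWHM_SIGMA_FACTOR / 0.05
        analytic = np.sum(2 * np.pi * sigmas_px**2 * peaks)
        assert total == pytest.approx(analytic, rel=0.01)

    def test_out_of_margin_particles_reported(self):
        cfg = _free_config(duration_s=1 / 512)
        t = simulate_trajectories(
            1,
            MotionModel("free", 0.0),
            cfg,
            initial_positions_um=[[0.1, 1.0]],
            diameters_um=[1.0],
        )
        with pytest.raises(ParticleOutOfBoundsError) as exc:
            render_stack(t, noise_sd=0.0)
        assert 0 in exc.value.particle_ids


class TestFixtures:
    def test_free_preset_emits_5120_frames(self):
        bundle = make_fixture("free_jurkat_like")
        assert bundle.config.n_frames == 5120
        assert bundle.config.frame_rate_hz == 512.0
        assert bundle.stack.shape[0] == 5120
        assert bundle.truth.positions_um.shape[1] == 5120
        del bundle

    def test_fixture_is_bit_identical_across_calls(self, drifting_bundle):
        again = make_fixture("drifting")
        assert np.array_equal(drifting_bundle.stack, again.stack)

    def test_confined_preset_carries_relaxation_time(self, confined_bundle):
        assert confined_bundle.truth.model.relaxation_time_s == 0.02

    def test_unknown_preset_rejected(self):
        with pytest.raises(KeyError):
            make_fixture("nonexistent")

    def test_fixture_written_to_disk(self, tmp_path):
        make_fixture("drifting", outdir=tmp_path)
        assert (tmp_path / "drifting.tif").exists()
        assert (tmp_path / "drifting_truth.csv").exists()
        assert (tmp_path / "drifting_config.json").exists()
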