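"""Descriptors, matching, trajectory QC and drift correction."""

import numpy as np
import pandas as pd
import pytest

from chromorheo import (
    AcquisitionConfig,
    MotionModel,
    center_of_mass,
    compute_descriptors,
    drift_correct,
    ensemble_msd,
    estimate_rigid_transform,
    link_spots,
    locate_spots,
    match_frames,
    qc_filter,
    render_stack,
    simulate_trajectories,
)
from chromorheo.tracking import apply_qc


def _two_spot_frame(seed=5):
    """Rendered frame with two spots (asymmetric neighborhoods)."""
    cfg = AcquisitionConfig(
        image_shape=(200, 200), duration_s=1 / 512, frame_rate_hz=512.0, seed=seed
    )
    truth = simulate_trajectories(
        2,
        MotionModel("free", 0.0),
        cfg,
        initial_positions_um=[[5.0, 5.0], [6.5, 5.6]],
        diameters_um=[1.0, 0.8],
        peak_intensities=[600.0, 400.0],
    )
    return render_stack(truth, noise_sd=0.0)[0]


def _traj_df(xy, diam=1.0, inten=100.0):
    xy = np.asarray(xy, dtype=float)
    n = len(xy)
    diam = np.broadcast_to(np.asarray(diam, dtype=float), n)
    inten = np.broadcast_to(np.asarray(inten, dtype=float), n)
    return pd.DataFrame(
        {
            "particle_id": 0,
            "frame": np.arange(n),
            "x_um": xy[:, 0],
            "y_um": xy[:, 1],
            "diameter_um": diam,
            "intensity": inten,
        }
    )


class TestDescriptors:
    def test_identical_frames_give_identical_descriptors(self):
        frame = _two_spot_frame()
        spots = locate_spots(frame)
        d1 = compute_descriptors(frame, spots)
        d2 = compute_descriptors(frame.copy(), spots)
        assert np.array_equal(d1.vectors, d2.vectors)

    def test_rotation_invariance_90_degrees(self):
        frame = _two_spot_frame()
        spots = locate_spots(frame)
        rot = np.rot90(frame)
        spots_rot = locate_spots(rot)
        d = compute_descriptors(frame, spots)
        dr = compute_descriptors(rot, spots_rot)
        assert d.valid.all() and dr.valid.all()
        for i in range(len(spots)):
            j = (spots_rot["diameter_um"] - spots["diameter_um"].iloc[i]).abs().idxmin()
            assert np.linalg.norm(d.vectors[i] - dr.vectors[j]) < 0.2

    def test_contrast_invariance(self):
        frame = _two_spot_frame()
        spots = locate_spots(frame)
        d1 = compute_descriptors(frame, spots)
        d2 = compute_descriptors(frame * 2.0, spots)
        assert np.nanmax(np.abs(d1.vectors - d2.vectors)) < 1e-6

    def test_border_spot_flagged_absent(self):
        frame = _two_spot_frame()
        spots = locate_spots(frame)
        near_border = spots.copy()
        near_border.loc[:, ["x_um", "y_um"]] = 0.3  # anchor in the corner
        d = compute_descriptors(frame, near_border)
        assert not d.valid.any()


class TestMatching:
    def test_static_spots_match_themselves(self):
        frame = _two_spot_frame()
        spots = locate_spots(frame)
        d = compute_descriptors(frame, spots)
        m = match_frames(spots, spots, d, d, max_disp_um=0.5)
        assert m.tolist() == [[0, 0], [1, 1]]

    def test_disjoint_spot_sets_give_no_matches(self):
        a = pd.DataFrame({"x_um": [1.0], "y_um": [1.0], "diameter_um": [1.0]})
        b = pd.DataFrame({"x_um": [9.0], "y_um": [9.0], "diameter_um": [1.0]})
        assert len(match_frames(a, b, max_disp_um=0.5)) == 0

    def test_matching_is_symmetric(self, rng):
        a = pd.DataFrame(
            {"x_um": rng.uniform(0, 10, 8), "y_um": rng.uniform(0, 10, 8)}
        )
        b = a + rng.normal(0, 0.02, (8, 2))
        m_ab = match_frames(a, b, max_disp_um=0.2)
        m_ba = match_frames(b, a, max_disp_um=0.2)
        assert sorted(map(tuple, m_ab)) == sorted((j, i) for i, j in m_ba)

    def test_fixture_links_agree_with_ground_truth(self, drifting_bundle):
        """>99% of frame-to-frame links recover true particle identities."""
        from scipy.spatial.distance import cdist

        bundle = drifting_bundle
        stack = bundle.stack[:64]
        spots = pd.concat(
            [locate_spots(stack[f], frame_index=f) for f in range(len(stack))],
            ignore_index=True,
        )
        linked = link_spots(stack, spots)
        ok = tot = 0
        id_map = {}
        for f, g in linked.groupby("frame"):
            d = cdist(g[["x_um", "y_um"]], bundle.truth.positions_um[:, int(f), :])
            true_ids = d.argmin(axis=1)
            if f == 0:
                id_map = dict(zip(g["particle_id"], true_ids))
            else:
                for pid, tid in zip(g["particle_id"], true_ids):
                    tot += 1
                    ok += id_map.get(pid, -1) == tid
        assert tot > 0 and ok / tot > 0.99


class TestQCFilter:
    def test_step_growing_by_60_percent_discarded(self):
        # steps 1.0 then 1.6: |1.6 - 1.0| = 0.6 > 0.5 * 1.0
        traj = _traj_df([[0, 0], [1, 0], [2.6, 0]])
        kept, status, reason = qc_filter(traj, min_length=2)
        assert reason == "displacement_jump"
        assert status == "accepted" and len(kept) == 2

    def test_step_within_50_percent_kept(self):
        traj = _traj_df([[0, 0], [1, 0], [2.4, 0], [3.5, 0]])
        kept, status, reason = qc_filter(traj, min_length=3)
        assert status == "accepted" and len(kept) == 4

    def test_diameter_5_percent_change_kept(self):
        traj = _traj_df([[0, 0], [0.1, 0], [0.2, 0]], diam=[1.00, 1.05, 1.05])
        kept, status, reason = qc_filter(traj, displacement_mode="off", min_length=3)
        assert status == "accepted" and len(kept) == 3

    def test_intensity_15_percent_change_discarded(self):
        traj = _traj_df([[0, 0], [0.1, 0], [0.2, 0]], inten=[100.0, 115.0, 115.0])
        kept, status, reason = qc_filter(traj, displacement_mode="off", min_length=3)
        assert status == "discarded" and reason == "intensity_jump"

    def test_step_ratio_mode_only_flags_growth(self):
        # step shrinking 1.0 -> 0.3 violates step_change but not step_ratio
        traj = _traj_df([[0, 0], [1, 0], [1.3, 0]])
        _, _, reason_change = qc_filter(traj, min_length=2)
        _, status_ratio, _ = qc_filter(
            traj, displacement_mode="step_ratio", min_length=3
        )
        assert reason_change == "displacement_jump"
        assert status_ratio == "accepted"

    def test_short_trajectory_discarded(self):
        traj = _traj_df([[0, 0], [1, 0]])
        _, status, reason = qc_filter(traj)
        assert status == "discarded" and reason == "too_short"

    def test_apply_qc_order_independent(self, rng):
        frames = np.arange(80)
        parts = []
        for pid in range(4):
            xy = np.cumsum(rng.normal(0, 0.01, (80, 2)), axis=0)
            df = _traj_df(xy)
            df["particle_id"] = pid
            parts.append(df)
        table = pd.concat(parts, ignore_index=True)
        shuffled = table.sample(frac=1.0, random_state=1).reset_index(drop=True)
        out1 = apply_qc(table, displacement_mode="off")
        out2 = apply_qc(shuffled, displacement_mode="off")
        pd.testing.assert_frame_equal(out1, out2)


class TestCenterOfMass:
    def test_weighted_mean(self):
        df = pd.DataFrame(
            {"x_um": [0.0, 2.0], "y_um": [0.0, 0.0], "intensity": [1.0, 3.0]}
        )
        assert center_of_mass(df).tolist() == [1.5, 0.0]

    def test_single_spot_is_its_own_com(self):
        df = pd.DataFrame({"x_um": [3.3], "y_um": [4.4], "intensity": [5.0]})
        assert center_of_mass(df).tolist() == [3.3, 4.4]

    def test_equal_weights_give_centroid(self):
        df = pd.DataFrame(
            {"x_um": [0.0, 1.0, 2.0], "y_um": [0.0, 3.0, 0.0], "intensity": [2.0] * 3}
        )
        assert np.allclose(center_of_mass(df), [1.0, 1.0])

    def test_zero_intensity_rejected(self):
        df = pd.DataFrame({"x_um": [0.0], "y_um": [0.0], "intensity": [0.0]})
        with pytest.raises(ValueError):
            center_of_mass(df)


class TestRigidTransform:
    def test_constructed_90_degree_motion_recovered_exactly(self):
        a = np.array([[0, 0], [1, 0], [0, 1]], dtype=float)
        b = np.array([[2, 3], [2, 4], [1, 3]], dtype=float)
        rot, t = estimate_rigid_transform(a, b)
        assert np.allclose(rot, [[0, -1], [1, 0]], atol=1e-12)
        assert np.allclose(t, [2, 3], atol=1e-12)
        assert np.max(np.abs(a @ rot.T + t - b)) < 1e-10

    def test_identical_point_sets_give_identity(self):
        a = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 0.0]])
        rot, t = estimate_rigid_transform(a, a)
        assert np.allclose(rot, np.eye(2), atol=1e-12)
        assert np.allclose(t, 0, atol=1e-12)

    def test_reflection_branch_corrected(self):
        a = np.array([[0, 0], [1, 0], [0, 1], [2, 2]], dtype=float)
        b = a[:, ::-1].copy()  # mirror image cannot be fit by a rotation
        rot, _ = estimate_rigid_transform(a, b)
        assert np.linalg.det(rot) == pytest.approx(1.0)

    def test_noisy_rotation_recovered_within_tenth_degree(self, rng):
        theta = np.deg2rad(17.0)
        rot_true = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        a = rng.uniform(0, 50, (50, 2))
        b = a @ rot_true.T + [3.0, -2.0] + rng.normal(0, 0.01, (50, 2))
        rot, _ = estimate_rigid_transform(a, b)
        angle = np.arctan2(rot[1, 0], rot[0, 0])
        assert abs(np.rad2deg(angle) - 17.0) < 0.1

    def test_single_pair_warns_and_returns_identity(self):
        with pytest.warns(UserWarning):
            rot, t = estimate_rigid_transform([[1.0, 1.0]], [[2.0, 2.0]])
        assert np.allclose(rot, np.eye(2)) and np.allclose(t, 0)


class TestDriftCorrect:
    @staticmethod
    def _table_from_truth(positions_um):
        n_p, n_f, _ = positions_um.shape
        return pd.DataFrame(
            {
                "particle_id": np.repeat(np.arange(n_p), n_f),
                "frame": np.tile(np.arange(n_f), n_p),
                "x_um": positions_um[:, :, 0].ravel(),
                "y_um": positions_um[:, :, 1].ravel(),
                "diameter_um": 1.0,
                "intensity": 100.0,
            }
        )

    def test_constant_translation_removed(self):
        base = np.array([[1.0, 1.0], [4.0, 1.0], [2.0, 3.0]])
        n_f = 10
        drift = np.arange(n_f)[:, None] * np.array([0.25, 0.25])
        pos = base[:, None, :] + drift[None, :, :]
        corrected, record = drift_correct(self._table_from_truth(pos))
        # corrected displacements vanish: motion was pure collective drift
        for _, g in corrected.groupby("particle_id"):
            d = np.diff(g[["x_corr_um", "y_corr_um"]].to_numpy(), axis=0)
            assert np.max(np.abs(d)) < 1e-10
        assert np.allclose(record["tx_um"].iloc[1:], 0.25)

    def test_single_particle_com_correction_zeroes_trajectory(self):
        pos = np.cumsum(np.random.default_rng(0).normal(0, 0.1, (1, 20, 2)), axis=1)
        corrected, _ = drift_correct(self._table_from_truth(pos), order="com_only")
        assert np.max(np.abs(corrected[["x_corr_um", "y_corr_um"]].to_numpy())) < 1e-12

    def test_global_rigid_motion_invariance(self):
        """An arbitrary per-frame rigid motion applied on top of Brownian
        paths leaves the corrected MSD unchanged (rigid equivariance of
        the Kabsch estimate)."""
        cfg = AcquisitionConfig(
            image_shape=(64, 64), duration_s=1.0, frame_rate_hz=256.0, seed=12
        )
        truth = simulate_trajectories(
            20,
            MotionModel("free", 0.02),
            cfg,
            initial_positions_um=np.tile([[5.0, 5.0]], (20, 1))
            + np.random.default_rng(3).uniform(-2, 2, (20, 2)),
        )
        pos = truth.positions_um
        n_f = pos.shape[1]
        thetas = 0.002 * np.arange(n_f)
        shifts = np.column_stack([0.01 * np.arange(n_f), -0.005 * np.arange(n_f)])
        moved = np.empty_like(pos)
        for f in range(n_f):
            c, s = np.cos(thetas[f]), np.sin(thetas[f])
            rot = np.array([[c, -s], [s, c]])
            moved[:, f, :] = pos[:, f, :] @ rot.T + shifts[f]
        base_corr, _ = drift_correct(self._table_from_truth(pos))
        moved_corr, _ = drift_correct(self._table_from_truth(moved))

        def msd_of(df):
            arr = np.stack(
                [
                    g.sort_values("frame")[["x_corr_um", "y_corr_um"]].to_numpy()
                    for _, g in df.groupby("particle_id")
                ]
            )
            return ensemble_msd(arr, 1 / 256.0, lags=np.arange(1, 30))

        m1, m2 = msd_of(base_corr), msd_of(moved_corr)
        assert np.allclose(m1.msd_um2, m2.msd_um2, rtol=1e-6)

    def test_missing_frame_com_interpolated(self):
        pos = np.tile(np.array([[1.0, 1.0], [3.0, 3.0]])[:, None, :], (1, 5, 1))
        table = self._table_from_truth(pos)
        table = table[table["frame"] != 2]
        _, record = drift_correct(table, order="com_only")
        assert bool(record.loc[record["frame"] == 2, "com_interpolated"].iloc[0])
        assert np.isclose(record.loc[record["frame"] == 2, "com_x_um"].iloc[0], 2.0)
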