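"""Ground-truth trajectory simulation and synthetic image rendering.

The generator emulates the acquisition used for nuclear-granule tracking:
phase-contrast-like movies of bright, diffraction-limited granules
(symmetric 2D-Gaussian profiles, optical diameters 0.5-1.5 um) sampled at
high frame rate (default 512 Hz for 10 s, 50 nm pixels).  Three motion
models are provided:

``free``
    2D Brownian motion; per-axis increments are i.i.d. Gaussian with
    variance ``2*D*dt``, so the 2D MSD is ``4*D*tau``.
``confined``
    Exact-discretization Ornstein-Uhlenbeck motion about a fixed tether
    point, the tracer analogue of a Kelvin-Voigt (spring-and-dashpot)
    medium.  The per-axis stationary variance is ``D*tau_r``, giving a 2D
    MSD plateau of ``4*D*tau_r`` and relaxation ``MSD(tau) =
    4*D*tau_r*(1 - exp(-tau/tau_r))``.
``drifting``
    Free motion plus a rigid translation ``v*t`` applied identically to
    every particle, emulating collective motion of the whole nucleus.

The exact OU update ``x(t+dt) = x(t)*exp(-dt/tau_r) + xi`` with
``Var(xi) = D*tau_r*(1 - exp(-2*dt/tau_r))`` is used instead of an Euler
scheme so that plateau values are unbiased at any step size.

Randomness derives from one master seed through ``numpy`` seed-sequence
spawning: stream 0 seeds particle initialization, stream 1 the motion,
stream 2 the pixel noise.  ``free`` and ``drifting`` consume the motion
stream identically, so two fixtures differing only by drift share their
Brownian paths — drift-correction tests can compare them pathwise.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from chromorheo.constants import FWHM_SIGMA_FACTOR

__all__ = [
    "AcquisitionConfig",
    "MotionModel",
    "GroundTruth",
    "simulate_trajectories",
    "render_stack",
    "make_fixture",
    "FIXTURE_PRESETS",
]


@dataclass(frozen=True)
class AcquisitionConfig:
    """Acquisition geometry and timing.

    Defaults follow a fast-camera phase-contrast setup: 50 nm effective
    pixels, 512 Hz for 10 s (5120 frames), room temperature.
    """

    pixel_size_um: float = 0.05
    frame_rate_hz: float = 512.0
    duration_s: float = 10.0
    image_shape: tuple[int, int] = (512, 512)
    temperature_k: float = 298.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.pixel_size_um > 0):
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if not (self.frame_rate_hz > 0):
            raise ValueError(f"frame_rate_hz must be > 0, got {self.frame_rate_hz}")
        if not (self.duration_s > 0):
            raise ValueError(f"duration_s must be > 0, got {self.duration_s}")
        if not (self.temperature_k > 0):
            raise ValueError(f"temperature_k must be > 0, got {self.temperature_k}")

    @property
    def dt_s(self) -> float:
        return 1.0 / self.frame_rate_hz

    @property
    def n_frames(self) -> int:
        return int(round(self.frame_rate_hz * self.duration_s))

    @property
    def fov_um(self) -> tuple[float, float]:
        """Field of view (height, width) in micrometres."""
        return (
            self.image_shape[0] * self.pixel_size_um,
            self.image_shape[1] * self.pixel_size_um,
        )


@dataclass(frozen=True)
class MotionModel:
    """Stochastic motion model of the granules.

    ``relaxation_time_s`` is the Kelvin-Voigt relaxation time
    ``tau_r = eta / G'`` and is required for ``kind='confined'``;
    ``drift_velocity_um_s`` applies to ``kind='drifting'`` only.
    """

    kind: str = "free"
    diffusion_um2_s: float = 0.1
    relaxation_time_s: float | None = None
    drift_velocity_um_s: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.kind not in ("free", "confined", "drifting"):
            raise ValueError(f"unknown motion kind {self.kind!r}")
        if not np.isfinite(self.diffusion_um2_s) or self.diffusion_um2_s < 0:
            raise ValueError("diffusion_um2_s must be finite and >= 0")
        if self.kind == "confined":
            if self.relaxation_time_s is None or not (
                np.isfinite(self.relaxation_time_s) and self.relaxation_time_s > 0
            ):
                raise ValueError("confined motion requires relaxation_time_s > 0")
        if not np.all(np.isfinite(self.drift_velocity_um_s)):
            raise ValueError("drift_velocity_um_s must be finite")


@dataclass
class GroundTruth:
    """True per-particle trajectories plus the parameters that made them.

    ``positions_um`` has shape ``(n_particles, n_frames, 2)`` with columns
    (x, y); positions include any applied drift.  ``drift_um`` is the
    cumulative rigid translation applied per frame (zeros unless the model
    drifts).
    """

    positions_um: np.ndarray
    diameters_um: np.ndarray
    peak_intensities: np.ndarray
    drift_um: np.ndarray
    model: MotionModel
    config: AcquisitionConfig

    @property
    def n_particles(self) -> int:
        return self.positions_um.shape[0]

    @property
    def n_frames(self) -> int:
        return self.positions_um.shape[1]

    def to_dataframe(self, nucleus_id: str = "synthetic") -> pd.DataFrame:
        n_p, n_f, _ = self.positions_um.shape
        idx_p = np.repeat(np.arange(n_p), n_f)
        idx_f = np.tile(np.arange(n_f), n_p)
        return pd.DataFrame(
            {
                "nucleus_id": nucleus_id,
                "particle_id": idx_p,
                "frame": idx_f,
                "x_um": self.positions_um[:, :, 0].ravel(),
                "y_um": self.positions_um[:, :, 1].ravel(),
                "diameter_um": self.diameters_um[idx_p],
                "intensity": self.peak_intensities[idx_p],
            }
        )


def _spawn_rngs(seed: int) -> tuple[np.random.Generator, np.random.Generator, np.random.Generator]:
    init_ss, motion_ss, noise_ss = np.random.SeedSequence(seed).spawn(3)
    return (
        np.random.default_rng(init_ss),
        np.random.default_rng(motion_ss),
        np.random.default_rng(noise_ss),
    )


def _default_initial_positions(
    n_particles: int,
    diameters_um: np.ndarray,
    config: AcquisitionConfig,
    rng: np.random.Generator,
    margin_um: float | None = None,
    min_separation_um: float = 0.0,
) -> np.ndarray:
    """Uniform initial positions with a safety margin and optional minimum
    pairwise separation (rejection sampling)."""
    h_um, w_um = config.fov_um
    sigma_max = diameters_um.max() / FWHM_SIGMA_FACTOR
    if margin_um is None:
        margin_um = 5.0 * sigma_max
    if 2 * margin_um >= min(h_um, w_um):
        raise ValueError(
            f"margin {margin_um:.2f} um leaves no interior in a "
            f"{h_um:.2f} x {w_um:.2f} um field"
        )
    pos = np.empty((n_particles, 2))
    for i in range(n_particles):
        for _ in range(10_000):
            cand = np.array(
                [
                    rng.uniform(margin_um, w_um - margin_um),
                    rng.uniform(margin_um, h_um - margin_um),
                ]
            )
            if i == 0 or np.min(np.linalg.norm(pos[:i] - cand, axis=1)) >= min_separation_um:
                pos[i] = cand
                break
        else:
            raise RuntimeError("could not place particles with requested separation")
    return pos


def simulate_trajectories(
    n_particles: int,
    model: MotionModel,
    config: AcquisitionConfig,
    *,
    initial_positions_um: np.ndarray | None = None,
    diameters_um: np.ndarray | None = None,
    peak_intensities: np.ndarray | None = None,
    init_margin_um: float | None = None,
    min_separation_um: float = 0.0,
) -> GroundTruth:
    """Simulate ground-truth 2D trajectories under ``model``.

    Per-axis dynamics:

    * free / drifting: ``x_{t+1} = x_t + N(0, sqrt(2*D*dt))``; drifting
      additionally adds the cumulative ``v*t`` to every particle.
    * confined: exact OU about the initial (tether) position with
      relaxation ``tau_r`` and stationary per-axis variance ``D*tau_r``;
      the initial offset is drawn from the stationary distribution.

    Reproducible for a fixed ``config.seed``.
    """
    if n_particles < 1:
        raise ValueError("n_particles must be >= 1")
    init_rng, motion_rng, _ = _spawn_rngs(config.seed)
    n_frames = config.n_frames
    dt = config.dt_s
    D = model.diffusion_um2_s

    if diameters_um is None:
        diameters_um = init_rng.uniform(0.5, 1.5, size=n_particles)
    else:
        diameters_um = np.asarray(diameters_um, dtype=float)
        init_rng.uniform(0.5, 1.5, size=n_particles)  # keep stream alignment
    if peak_intensities is None:
        peak_intensities = init_rng.uniform(400.0, 800.0, size=n_particles)
    else:
        peak_intensities = np.asarray(peak_intensities, dtype=float)
        init_rng.uniform(400.0, 800.0, size=n_particles)
    if initial_positions_um is None:
        centers = _default_initial_positions(
            n_particles, diameters_um, config, init_rng,
            margin_um=init_margin_um, min_separation_um=min_separation_um,
        )
    else:
        centers = np.asarray(initial_positions_um, dtype=float).reshape(n_particles, 2)

    positions = np.empty((n_particles, n_frames, 2))
    drift = np.zeros((n_frames, 2))

    if model.kind in ("free", "drifting"):
        steps = motion_rng.normal(
            0.0, np.sqrt(2.0 * D * dt), size=(n_particles, n_frames - 1, 2)
        )
        positions[:, 0] = centers
        positions[:, 1:] = centers[:, None, :] + np.cumsum(steps, axis=1)
        if model.kind == "drifting":
            t = np.arange(n_frames)[:, None] * dt
            drift = t * np.asarray(model.drift_velocity_um_s)
            positions += drift[None, :, :]
    else:  # confined OU
        tau = model.relaxation_time_s
        a = np.exp(-dt / tau)
        stat_sd = np.sqrt(D * tau)
        step_sd = np.sqrt(D * tau * (1.0 - a * a))
        offsets = motion_rng.normal(0.0, stat_sd, size=(n_particles, 2))
        noise = motion_rng.normal(0.0, step_sd, size=(n_particles, n_frames - 1, 2))
        # OU recursion x_{t+1} = a*x_t + xi as an IIR filter along time
        from scipy.signal import lfilter

        x = np.concatenate([offsets[:, None, :], noise], axis=1)
        ou = lfilter([1.0], [1.0, -a], x, axis=1)
        # lfilter computes y_t = x_t + a*y_{t-1}; y_0 = offsets as required
        positions = centers[:, None, :] + ou

    if not np.all(np.isfinite(positions)):
        raise FloatingPointError("non-finite positions generated")
    return GroundTruth(
        positions_um=positions,
        diameters_um=diameters_um,
        peak_intensities=peak_intensities,
        drift_um=drift,
        model=model,
        config=config,
    )


class ParticleOutOfBoundsError(ValueError):
    """A particle approaches the image border closer than the 3-sigma
    rendering margin; rendering would clip its profile."""

    def __init__(self, particle_ids: np.ndarray):
        self.particle_ids = np.asarray(particle_ids)
        super().__init__(
            f"particles {self.particle_ids.tolist()} leave the 3-sigma rendering margin"
        )


def render_stack(
    truth: GroundTruth,
    config: AcquisitionConfig | None = None,
    *,
    background: float = 100.0,
    noise_sd: float = 0.0,
    dtype=np.float64,
) -> np.ndarray:
    """Render ground truth as an image stack of symmetric 2D Gaussians.

    Each particle contributes ``I_peak * exp(-((x-x0)^2+(y-y0)^2)/(2 sigma^2))``
    with ``sigma = diameter / (2 sqrt(2 ln 2))`` (diameter = FWHM).  Pixel
    centers sit at integer coordinates; physical position (um) maps to
    pixel coordinate as ``px = um / pixel_size``.  Additive constant
    background plus i.i.d. Gaussian pixel noise; negative values are
    clipped at zero before any integer cast.

    Raises :class:`ParticleOutOfBoundsError` listing the offending
    particles if any position comes within 3 sigma of the border.
    """
    if config is None:
        config = truth.config
    h, w = config.image_shape
    px = config.pixel_size_um
    sigmas_um = truth.diameters_um / FWHM_SIGMA_FACTOR
    sigmas_px = sigmas_um / px

    pos_px = truth.positions_um / px  # (n_p, n_f, 2) as (x, y)
    lo = 3.0 * sigmas_px[:, None]
    bad = (
        (pos_px[:, :, 0] < lo)
        | (pos_px[:, :, 0] > (w - 1) - lo)
        | (pos_px[:, :, 1] < lo)
        | (pos_px[:, :, 1] > (h - 1) - lo)
    )
    if bad.any():
        raise ParticleOutOfBoundsError(np.nonzero(bad.any(axis=1))[0])

    _, _, noise_rng = _spawn_rngs(config.seed)
    n_frames = truth.n_frames
    stack = np.empty((n_frames, h, w), dtype=dtype)
    half = np.ceil(4.0 * sigmas_px).astype(int)
    for f in range(n_frames):
        if noise_sd > 0:
            frame = noise_rng.normal(background, noise_sd, size=(h, w))
        else:
            frame = np.full((h, w), background, dtype=float)
        for p in range(truth.n_particles):
            x0, y0 = pos_px[p, f]
            s = sigmas_px[p]
            hw = half[p]
            c0, c1 = int(np.floor(x0)) - hw, int(np.floor(x0)) + hw + 1
            r0, r1 = int(np.floor(y0)) - hw, int(np.floor(y0)) + hw + 1
            c0, c1 = max(c0, 0), min(c1, w)
            r0, r1 = max(r0, 0), min(r1, h)
            yy, xx = np.mgrid[r0:r1, c0:c1]
            frame[r0:r1, c0:c1] += truth.peak_intensities[p] * np.exp(
                -((xx - x0) ** 2 + (yy - y0) ** 2) / (2.0 * s * s)
            )
        np.clip(frame, 0.0, None, out=frame)
        stack[f] = frame.astype(dtype) if dtype != np.float64 else frame
    if np.issubdtype(np.dtype(dtype), np.integer):
        info = np.iinfo(dtype)
        stack = np.clip(stack, info.min, info.max).astype(dtype)
    return stack


#: Named deterministic fixtures.  ``free_jurkat_like`` keeps the full
#: acquisition length (512 Hz x 10 s = 5120 frames); the confined and
#: drifting presets are shorter so end-to-end tests stay fast.
FIXTURE_PRESETS: dict[str, dict] = {
    "free_jurkat_like": dict(
        config=AcquisitionConfig(
            image_shape=(320, 320), duration_s=10.0, frame_rate_hz=512.0, seed=11
        ),
        model=MotionModel(kind="free", diffusion_um2_s=0.01),
        n_particles=5,
        diameters_um=(0.7, 0.9, 1.1, 1.3, 0.8),
        peak_intensities=(600.0,) * 5,
        init_margin_um=4.5,
        min_separation_um=3.0,
        background=100.0,
        noise_sd=60.0,  # peak SNR = 10 (600 over sd 60)
    ),
    "confined_voigt": dict(
        config=AcquisitionConfig(
            image_shape=(320, 320), duration_s=2.0, frame_rate_hz=512.0, seed=23
        ),
        model=MotionModel(kind="confined", diffusion_um2_s=0.01, relaxation_time_s=0.02),
        n_particles=8,
        diameters_um=(0.6, 0.8, 1.0, 1.2, 1.4, 0.9, 1.1, 0.7),
        peak_intensities=(600.0,) * 8,
        init_margin_um=4.0,
        min_separation_um=3.0,
        background=100.0,
        noise_sd=60.0,
    ),
    "drifting": dict(
        config=AcquisitionConfig(
            image_shape=(320, 320), duration_s=0.5, frame_rate_hz=512.0, seed=37
        ),
        model=MotionModel(
            kind="drifting", diffusion_um2_s=0.01, drift_velocity_um_s=(1.2, 0.8)
        ),
        n_particles=5,
        diameters_um=(0.7, 0.9, 1.1, 1.3, 0.8),
        peak_intensities=(600.0,) * 5,
        init_margin_um=4.5,
        min_separation_um=3.0,
        background=100.0,
        noise_sd=0.0,  # noise-free: drift-correction oracle fixture
    ),
}


@dataclass
class FixtureBundle:
    name: str
    stack: np.ndarray
    truth: GroundTruth
    config: AcquisitionConfig
    background: float
    noise_sd: float


def make_fixture(
    name: str,
    outdir: str | Path | None = None,
    duration_s: float | None = None,
) -> FixtureBundle:
    """Build a named deterministic fixture (stack + ground truth + config).

    With ``outdir`` the bundle is written to disk: multi-page 16-bit TIFF,
    ground-truth CSV and a JSON sidecar with the full configuration.
    Calling twice with the same name yields bit-identical stacks.
    ``duration_s`` shortens (or extends) the preset acquisition while
    keeping everything else fixed.
    """
    if name not in FIXTURE_PRESETS:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(FIXTURE_PRESETS)}"
        )
    p = FIXTURE_PRESETS[name]
    config = p["config"]
    if duration_s is not None:
        config = AcquisitionConfig(
            pixel_size_um=config.pixel_size_um,
            frame_rate_hz=config.frame_rate_hz,
            duration_s=duration_s,
            image_shape=tuple(config.image_shape),
            temperature_k=config.temperature_k,
            seed=config.seed,
        )
    truth = simulate_trajectories(
        p["n_particles"],
        p["model"],
        config,
        diameters_um=p.get("diameters_um"),
        peak_intensities=p.get("peak_intensities"),
        init_margin_um=p["init_margin_um"],
        min_separation_um=p["min_separation_um"],
    )
    stack = render_stack(
        truth,
        config,
        background=p["background"],
        noise_sd=p["noise_sd"],
        dtype=np.uint16,
    )
    bundle = FixtureBundle(
        name=name,
        stack=stack,
        truth=truth,
        config=config,
        background=p["background"],
        noise_sd=p["noise_sd"],
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(outdir / f"{name}.tif", stack)
        truth.to_dataframe(nucleus_id=name).to_csv(
            outdir / f"{name}_truth.csv", index=False
        )
        meta = {
            "name": name,
            "config": asdict(config),
            "model": asdict(p["model"]),
            "background": p["background"],
            "noise_sd": p["noise_sd"],
        }
        (outdir / f"{name}_config.json").write_text(json.dumps(meta, indent=2))
    return bundle
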