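"""Time-averaged mean squared displacements, diffusion fits and the
Stokes-Einstein apparent viscosity.

For a drift-corrected trajectory r'(t) sampled at interval dt, the
time-averaged MSD at lag tau = k*dt is

    MSD(tau) = (1/n_k) * sum_j |r'(t_j + tau) - r'(t_j)|^2

over all n_k overlapping time origins t_j.  Free 2D diffusion obeys
MSD(tau) = 4 D tau at short lags; the effective diffusivity D_eff is the
slope of a weighted least-squares fit through the origin.  The apparent
viscosity follows from the Stokes-Einstein relation for stick boundary
conditions, D_eff = k_B T / (6 pi eta_app R), with R the optical radius
(half the fitted FWHM diameter).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from chromorheo.constants import BOLTZMANN_J_PER_K

__all__ = [
    "MSDCurve",
    "DiffusionFit",
    "ViscosityEstimate",
    "compute_msd",
    "ensemble_msd",
    "fit_diffusion",
    "fit_anomalous_exponent",
    "estimate_viscosity",
]


@dataclass
class MSDCurve:
    """MSD values on a lag-time grid.

    ``n_origins[k]`` counts the overlapping time origins averaged at lag
    ``lag_s[k]``; for an ensemble curve, ``se_um2`` holds the standard
    error across trajectories of the per-trajectory time averages.
    """

    lag_s: np.ndarray
    msd_um2: np.ndarray
    n_origins: np.ndarray
    dt_s: float
    se_um2: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(self.msd_um2 < 0):
            raise ValueError("MSD values must be non-negative")
        if np.any(np.diff(self.lag_s) <= 0):
            raise ValueError("lag times must be strictly increasing")


class DiffusionFit:
    """Result of the short-lag free-diffusion fit (slope/4 of MSD vs tau)."""

    __slots__ = ("d_um2_s", "d_stderr_um2_s", "clipped")

    def __init__(self, d_um2_s: float, d_stderr_um2_s: float, clipped: bool = False):
        self.d_um2_s = d_um2_s
        self.d_stderr_um2_s = d_stderr_um2_s
        self.clipped = clipped

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"DiffusionFit(d_um2_s={self.d_um2_s:.4g}, "
            f"d_stderr_um2_s={self.d_stderr_um2_s:.2g}, clipped={self.clipped})"
        )


@dataclass
class ViscosityEstimate:
    """Apparent viscosity from Stokes-Einstein inversion; ``infinite`` is
    set (and the value is inf) when D_eff = 0."""

    eta_app_pa_s: float
    uncertainty_pa_s: float
    d_eff_um2_s: float
    radius_um: float
    temperature_k: float
    infinite: bool = False


def _positions(trajectory) -> np.ndarray:
    """Accept an (n, 2) array or a trajectory DataFrame (preferring
    drift-corrected columns)."""
    if isinstance(trajectory, pd.DataFrame):
        traj = trajectory.sort_values("frame", kind="stable")
        if "x_corr_um" in traj.columns:
            return traj[["x_corr_um", "y_corr_um"]].to_numpy(dtype=float)
        return traj[["x_um", "y_um"]].to_numpy(dtype=float)
    return np.asarray(trajectory, dtype=float).reshape(-1, 2)


def compute_msd(
    trajectory,
    dt_s: float,
    max_lag_fraction: float = 0.25,
    lags: np.ndarray | None = None,
    overlapping: bool = True,
) -> MSDCurve:
    """Time-averaged MSD over all overlapping origins.

    ``lags`` (frame counts) overrides the default 1..floor(n*fraction)
    grid — log-spaced subsets keep long-trajectory batches cheap.
    ``overlapping=False`` strides the time origins by the lag, giving
    fewer but independent squared displacements (useful for variance
    estimation; the default maximizes data use).
    """
    pos = _positions(trajectory)
    n = len(pos)
    if n < 3:
        raise ValueError(f"trajectory too short for MSD ({n} frames)")
    if lags is None:
        kmax = min(max(int(np.floor(n * max_lag_fraction)), 1), n - 1)
        lags = np.arange(1, kmax + 1)
    else:
        lags = np.unique(np.asarray(lags, dtype=int))
        if lags.min() < 1 or lags.max() >= n:
            raise ValueError("lags must lie in [1, n_frames-1]")
    msd = np.empty(len(lags))
    n_origins = np.empty(len(lags), dtype=int)
    for i, k in enumerate(lags):
        d = pos[k:] - pos[:-k]
        if not overlapping:
            d = d[::k]
        msd[i] = np.mean(np.sum(d * d, axis=1))
        n_origins[i] = len(d)
    return MSDCurve(lag_s=lags * dt_s, msd_um2=msd, n_origins=n_origins, dt_s=dt_s)


def ensemble_msd(
    positions_um: np.ndarray,
    dt_s: float,
    max_lag_fraction: float = 0.25,
    lags: np.ndarray | None = None,
) -> MSDCurve:
    """Ensemble MSD of an ``(n_traj, n_frames, 2)`` position array:
    mean over trajectories of the per-trajectory time averages, with the
    across-trajectory standard error in ``se_um2``."""
    positions_um = np.asarray(positions_um, dtype=float)
    n_traj, n, _ = positions_um.shape
    if lags is None:
        kmax = max(int(np.floor(n * max_lag_fraction)), 1)
        lags = np.arange(1, kmax + 1)
    else:
        lags = np.unique(np.asarray(lags, dtype=int))
    per = np.empty((n_traj, len(lags)))
    n_origins = np.empty(len(lags), dtype=int)
    for i, k in enumerate(lags):
        d = positions_um[:, k:, :] - positions_um[:, :-k, :]
        per[:, i] = np.mean(np.sum(d * d, axis=2), axis=1)
        n_origins[i] = n - k
    mean = per.mean(axis=0)
    se = per.std(axis=0, ddof=1) / np.sqrt(n_traj) if n_traj > 1 else np.zeros(len(lags))
    return MSDCurve(
        lag_s=lags * dt_s, msd_um2=mean, n_origins=n_origins, dt_s=dt_s, se_um2=se
    )


def fit_diffusion(
    msd: MSDCurve, max_lag_s: float = 0.1, min_lags: int = 4,
    intercept: bool = False,
) -> DiffusionFit:
    """Fit ``MSD = 4 D tau`` through the origin over short lags.

    Weighted least squares with weights proportional to the number of
    origins per lag.  The default has no intercept, matching the
    short-lag free-diffusion law; ``intercept=True`` adds a free offset
    absorbing static localization noise.  A negative fitted slope is
    clipped to D = 0 and flagged.
    """
    m = msd.lag_s <= max_lag_s
    if m.sum() < min_lags:
        raise ValueError(
            f"only {int(m.sum())} lags <= {max_lag_s} s; need >= {min_lags}"
        )
    tau = msd.lag_s[m]
    y = msd.msd_um2[m]
    w = msd.n_origins[m].astype(float)
    if intercept:
        wm = w / w.sum()
        tbar = np.sum(wm * tau)
        ybar = np.sum(wm * y)
        sxx = np.sum(w * (tau - tbar) ** 2)
        slope = np.sum(w * (tau - tbar) * (y - ybar)) / sxx
        resid = y - ybar - slope * (tau - tbar)
        dof = max(len(tau) - 2, 1)
    else:
        sxx = np.sum(w * tau * tau)
        slope = np.sum(w * tau * y) / sxx
        resid = y - slope * tau
        dof = max(len(tau) - 1, 1)
    slope_var = np.sum(w * resid * resid) / dof / sxx
    d = slope / 4.0
    stderr = np.sqrt(slope_var) / 4.0
    if d < 0:
        return DiffusionFit(0.0, stderr, clipped=True)
    return DiffusionFit(d, stderr, clipped=False)


def fit_anomalous_exponent(
    msd: MSDCurve, lag_range_s: tuple[float, float] | None = None
) -> float:
    """Log-log slope of MSD vs lag over a lag window (whole curve by
    default).  Zero MSD values are excluded; fewer than 3 usable lags is
    an error."""
    m = msd.msd_um2 > 0
    if lag_range_s is not None:
        lo, hi = lag_range_s
        m &= (msd.lag_s >= lo) & (msd.lag_s <= hi)
    if m.sum() < 3:
        raise ValueError("fewer than 3 usable lags in window")
    lx = np.log(msd.lag_s[m])
    ly = np.log(msd.msd_um2[m])
    alpha = np.polyfit(lx, ly, 1)[0]
    return float(alpha)


def estimate_viscosity(
    d_eff_um2_s: float,
    radius_um: float,
    temperature_k: float,
    d_stderr_um2_s: float = 0.0,
) -> ViscosityEstimate:
    """Invert Stokes-Einstein: ``eta_app = k_B T / (6 pi D_eff R)``.

    D_eff in um^2/s and R in um are converted to SI internally; the
    result is in Pa*s.  The relative uncertainty of D propagates linearly
    to eta.  D_eff = 0 yields an infinite-viscosity flag (excluded from
    phenotype averages downstream).
    """
    if d_eff_um2_s < 0 or radius_um <= 0 or temperature_k <= 0:
        raise ValueError("D_eff must be >= 0 and R, T > 0")
    if d_eff_um2_s == 0:
        return ViscosityEstimate(
            np.inf, np.inf, d_eff_um2_s, radius_um, temperature_k, infinite=True
        )
    d_si = d_eff_um2_s * 1e-12
    r_si = radius_um * 1e-6
    eta = BOLTZMANN_J_PER_K * temperature_k / (6.0 * np.pi * d_si * r_si)
    unc = eta * (d_stderr_um2_s / d_eff_um2_s)
    return ViscosityEstimate(eta, unc, d_eff_um2_s, radius_um, temperature_k)
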