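"""Frequency-dependent viscoelastic moduli from MSD curves.

The generalized Stokes-Einstein relation (GSER) links the Laplace
transform of the tracer MSD to the complex shear modulus of the
surrounding medium.  Rather than evaluating the transform numerically,
the local power-law (Mason) approximation evaluates the modulus
magnitude algebraically from the MSD and its local log-log slope
``alpha(tau) = d ln MSD / d ln tau``:

    G_d(omega) ~= 2 k_B T / (3 pi R * MSD(tau) * Gamma(1 + alpha(tau))),
    omega = 1/tau,

with the phase angle from the log-slope of the modulus itself,

    delta(omega) ~= (pi/2) * d ln G_d / d ln omega.

Storage and loss moduli follow as G' = G_d cos(delta),
G'' = G_d sin(delta), and the dynamic viscosity as
eta(omega) = G''(omega) / omega.  For a pure power law MSD ~ tau^alpha
these formulas are exact in the exponents: delta = (pi/2) alpha and
G_d ~ omega^alpha.  The 2/(3 pi R) prefactor applies to the 2D (in-plane)
MSD; fed an exact free-diffusion MSD = 4 D tau it returns
eta(omega) = k_B T / (6 pi R D) = eta_app at every frequency, so the
spectral route and the Stokes-Einstein route agree by construction.

A tracer confined in a Kelvin-Voigt body (spring G' parallel to dashpot
eta) shows an MSD plateau A = 4 D tau_r; the plateau modulus is
G' = 2 k_B T / (3 pi R A) and the high-frequency viscosity recovers the
dashpot: :func:`fit_voigt` summarizes a spectrum this way.

Local log-log slopes are estimated by centered quadratic fits over a
5-point window (one-sided at the endpoints, which are flagged); raw
finite differences would amplify MSD noise.  Points whose MSD slope
leaves (-0.5, 1.5) are masked — the Gamma argument approaches a pole.

:func:`laplace_modulus` provides the direct numerical Laplace-transform
route for validation on exact inputs; it is not used by the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gamma as gamma_fn

from chromorheo.constants import BOLTZMANN_J_PER_K
from chromorheo.msd import MSDCurve

__all__ = [
    "RheologySpectrum",
    "VoigtFit",
    "mason_modulus",
    "laplace_modulus",
    "fit_voigt",
]


@dataclass
class RheologySpectrum:
    """Viscoelastic spectrum on the reciprocal-lag frequency grid.

    Arrays are ordered by increasing ``omega_rad_s`` (decreasing lag).
    ``masked`` marks points where the MSD log-slope neared the Gamma pole
    or the phase left [0, pi/2] by more than 5%; ``endpoint`` marks
    one-sided slope estimates at the grid ends.
    """

    omega_rad_s: np.ndarray
    gd_pa: np.ndarray
    delta_rad: np.ndarray
    gp_pa: np.ndarray
    gpp_pa: np.ndarray
    eta_pa_s: np.ndarray
    masked: np.ndarray
    endpoint: np.ndarray
    radius_um: float
    temperature_k: float


@dataclass
class VoigtFit:
    """Kelvin-Voigt summary of a spectrum: plateau rigidity G' (median of
    G' over the flat region), dashpot viscosity eta (mean of eta(omega)
    over the top half-decade of frequency), and the G''/G' ratio."""

    g_prime_pa: float
    eta_pa_s: float
    gpp_gp_ratio: float
    plateau_found: bool


def _local_loglog_slope(lx: np.ndarray, ly: np.ndarray, window: int = 5) -> np.ndarray:
    """Derivative dly/dlx at every point from quadratic fits over a
    centered window (truncated one-sided at the ends)."""
    n = len(lx)
    half = window // 2
    slopes = np.empty(n)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        x = lx[lo:hi] - lx[i]
        y = ly[lo:hi]
        if len(x) >= 3:
            c = np.polyfit(x, y, 2)
            slopes[i] = c[1]  # derivative of c0*x^2 + c1*x + c2 at x=0
        else:
            c = np.polyfit(x, y, 1)
            slopes[i] = c[0]
    return slopes


def mason_modulus(
    msd: MSDCurve,
    radius_um: float,
    temperature_k: float = 298.0,
    slope_window: int = 5,
) -> RheologySpectrum:
    """Evaluate the GSER in the local power-law approximation.

    Requires strictly positive MSD over the used lags.  The frequency
    grid is exactly the reciprocal of the measured lags (no resampling).
    """
    if radius_um <= 0 or temperature_k <= 0:
        raise ValueError("radius and temperature must be positive")
    pos = msd.msd_um2 > 0
    tau = msd.lag_s[pos]
    m_um2 = msd.msd_um2[pos]
    if len(tau) < 3:
        raise ValueError("need >= 3 positive-MSD lags for a spectrum")
    lt = np.log(tau)
    lm = np.log(m_um2)
    alpha = _local_loglog_slope(lt, lm, window=slope_window)
    endpoint = np.zeros(len(tau), dtype=bool)
    half = slope_window // 2
    endpoint[:half] = True
    endpoint[len(tau) - half :] = True

    masked = (alpha <= -0.5) | (alpha >= 1.5)
    alpha_safe = np.clip(alpha, -0.499, 1.499)

    kbt = BOLTZMANN_J_PER_K * temperature_k
    r_m = radius_um * 1e-6
    msd_m2 = m_um2 * 1e-12
    gd = 2.0 * kbt / (3.0 * np.pi * r_m * msd_m2 * gamma_fn(1.0 + alpha_safe))

    omega = 1.0 / tau
    # d ln Gd / d ln omega = - d ln Gd / d ln tau
    slope_g = -_local_loglog_slope(lt, np.log(gd), window=slope_window)
    delta_raw = 0.5 * np.pi * slope_g
    excursion = 0.05 * (np.pi / 2.0)
    masked |= (delta_raw < -excursion) | (delta_raw > np.pi / 2.0 + excursion)
    delta = np.clip(delta_raw, 0.0, np.pi / 2.0)

    gp = gd * np.cos(delta)
    gpp = gd * np.sin(delta)
    eta = gpp / omega

    order = np.argsort(omega)
    return RheologySpectrum(
        omega_rad_s=omega[order],
        gd_pa=gd[order],
        delta_rad=delta[order],
        gp_pa=gp[order],
        gpp_pa=gpp[order],
        eta_pa_s=eta[order],
        masked=masked[order],
        endpoint=endpoint[order],
        radius_um=radius_um,
        temperature_k=temperature_k,
    )


def laplace_modulus(
    msd: MSDCurve,
    radius_um: float,
    temperature_k: float = 298.0,
    s_grid: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Direct numerical Laplace-transform GSER (validation route).

    ``G(s) = 2 k_B T / (3 pi R s * L{MSD}(s))`` with the transform
    integrated by the trapezoid rule over the measured lag range (the
    MSD is anchored at MSD(0) = 0).  Accurate only for s well inside
    the reciprocal lag range; returns ``(s_grid, G(s))``.
    """
    pos = msd.msd_um2 > 0
    tau = np.concatenate([[0.0], msd.lag_s[pos]])
    m = np.concatenate([[0.0], msd.msd_um2[pos] * 1e-12])
    if s_grid is None:
        inner = msd.lag_s[pos]
        s_grid = 1.0 / inner[(inner > 3 * inner.min()) & (inner < inner.max() / 3)]
    s_grid = np.asarray(s_grid, dtype=float)
    kbt = BOLTZMANN_J_PER_K * temperature_k
    r_m = radius_um * 1e-6
    # linear extrapolation beyond the last lag keeps the truncated-tail
    # error small (exact for a linearly growing MSD)
    t_end = tau[-1]
    m_end = m[-1]
    slope_end = (m[-1] - m[-2]) / (tau[-1] - tau[-2]) if len(tau) > 1 else 0.0
    g = np.empty(len(s_grid))
    for i, s in enumerate(s_grid):
        lap = np.trapezoid(m * np.exp(-s * tau), tau)
        lap += np.exp(-s * t_end) * (m_end / s + slope_end / s**2)
        g[i] = 2.0 * kbt / (3.0 * np.pi * r_m * s * lap) if lap > 0 else np.nan
    return s_grid, g


def fit_voigt(spec: RheologySpectrum, flatness_tol: float = 0.2) -> VoigtFit:
    """Summarize a spectrum as a Kelvin-Voigt body.

    The plateau region is where the local log-slope of G'(omega) stays
    below ``flatness_tol`` in magnitude; without one (e.g. a purely
    viscous medium, where G' vanishes) the fit is flagged
    ``plateau_found=False``.  Requires at least one decade of frequency.
    """
    ok = ~spec.masked
    omega = spec.omega_rad_s[ok]
    gp = spec.gp_pa[ok]
    gpp = spec.gpp_pa[ok]
    eta = spec.eta_pa_s[ok]
    if len(omega) < 3 or omega.max() / omega.min() < 10.0:
        raise ValueError("spectrum must span at least one decade of frequency")

    gd_scale = np.median(spec.gd_pa[ok])
    usable = gp > 1e-9 * gd_scale
    plateau_found = False
    g_prime = 0.0
    flat = np.zeros(len(omega), dtype=bool)
    if usable.sum() >= 3:
        lsl = _local_loglog_slope(np.log(omega[usable]), np.log(gp[usable]))
        flat_u = np.abs(lsl) < flatness_tol
        if flat_u.sum() >= 3:
            plateau_found = True
            idx = np.nonzero(usable)[0][flat_u]
            flat[idx] = True
            # the plateau is the low-frequency limit; restrict to the
            # lowest half-decade of the flat region so shoulder points
            # (still relaxing toward the plateau) do not bias G' upward
            w_flat = omega[idx]
            low = idx[w_flat <= w_flat.min() * np.sqrt(10.0)]
            g_prime = float(np.median(gp[low]))
        else:
            g_prime = float(np.median(gp[usable]))
    high = omega >= omega.max() / np.sqrt(10.0)
    eta_fit = float(np.mean(eta[high]))
    if plateau_found:
        ratio = float(np.median(gpp[flat] / gp[flat]))
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            r = gpp[usable] / gp[usable] if usable.any() else np.array([np.inf])
        ratio = float(np.median(r))
    return VoigtFit(
        g_prime_pa=g_prime,
        eta_pa_s=eta_fit,
        gpp_gp_ratio=ratio,
        plateau_found=plateau_found,
    )
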