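"""Granule detection: candidate peaks and sub-pixel 2D-Gaussian fits.

Granules appear as highly contrasted, symmetric 2D-Gaussian spots on a
roughly uniform background.  Detection proceeds in two stages:

1. :func:`detect_candidates` — local maxima whose intensity exceeds the
   background (image median) by ``min_contrast`` robust standard
   deviations, separated by at least 3 px.
2. :func:`fit_gaussian` — least-squares fit of
   ``I0 + A * exp(-((x-x0)^2 + (y-y0)^2) / (2 sigma^2))`` on a square
   window around each candidate, giving sub-pixel position, optical
   diameter (Gaussian FWHM, ``2 sqrt(2 ln 2) sigma``) and integrated
   intensity (``2 pi sigma^2 A``, background-subtracted).

Coordinate convention: pixel centers at integer coordinates, x rightward
(columns), y downward (rows), origin at the top-left pixel; physical
position (um) = pixel coordinate * pixel size.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.optimize import least_squares
from skimage.feature import peak_local_max

from chromorheo.constants import FWHM_SIGMA_FACTOR

__all__ = [
    "Spot",
    "SpotFitError",
    "default_window_px",
    "detect_candidates",
    "fit_gaussian",
    "locate_spots",
    "locate_stack",
    "filter_by_diameter",
]


class Spot(NamedTuple):
    """One fitted granule in one frame.

    ``intensity`` is the integrated area of the fitted Gaussian
    (``2 pi sigma^2 A``), i.e. background-corrected optical density;
    ``fit_residual`` is the RMS fit residual normalized by the amplitude.
    """

    frame: int
    x_um: float
    y_um: float
    diameter_um: float
    intensity: float
    fit_residual: float


class SpotFitError(RuntimeError):
    """Gaussian fit failed (non-convergence or collapsed width)."""


def default_window_px(
    expected_diameter_um: float = 1.0, pixel_size_um: float = 0.05
) -> int:
    """Odd fit-window size covering ~3x the expected FWHM.

    A window much narrower than the spot makes the width unidentifiable;
    much wider ones swallow neighboring granules.  2x FWHM (~4.7 sigma)
    keeps the width identifiable while limiting neighbor-tail overlap.
    """
    fwhm_px = expected_diameter_um / pixel_size_um
    w = int(round(2.0 * fwhm_px))
    return max(w + (w + 1) % 2, 7)


def detect_candidates(
    frame: np.ndarray,
    min_contrast: float = 4.0,
    min_separation_px: int = 3,
    smooth_sigma_px: float = 2.0,
) -> np.ndarray:
    """Find candidate peak pixels in one frame.

    The frame is lightly Gaussian-smoothed (``smooth_sigma_px``, well
    below the spot width) so single-pixel noise cannot form maxima; the
    background level is the image median and its scale the median
    absolute deviation (scaled to a Gaussian sd), both computed on the
    smoothed image and robust to the bright spots themselves.  Returns an
    ``(N, 2)`` integer array of (row, col) peak positions; empty frames
    yield an empty result.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0:
        return np.empty((0, 2), dtype=int)
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame contains non-finite values")
    smooth = (
        gaussian_filter(frame, smooth_sigma_px) if smooth_sigma_px > 0 else frame
    )
    bg = np.median(smooth)
    sd = 1.4826 * np.median(np.abs(smooth - bg))
    # strictly-positive offset so a flat background never yields peaks
    threshold = bg + max(min_contrast * sd, 1e-6 * max(abs(bg), 1.0))
    if smooth.max() <= threshold:
        return np.empty((0, 2), dtype=int)
    # smoothing correlates noise at the image edge (reflect padding), so
    # exclude a thin border strip; border spots cannot be fit anyway
    border = max(min_separation_px, int(np.ceil(3 * smooth_sigma_px)))
    return peak_local_max(
        smooth,
        min_distance=min_separation_px,
        threshold_abs=threshold,
        exclude_border=border,
    )


def _gauss_model(params: np.ndarray, xx: np.ndarray, yy: np.ndarray) -> np.ndarray:
    i0, a, x0, y0, sigma = params
    return i0 + a * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2.0 * sigma**2))


def _gauss_jac(params: np.ndarray, xx: np.ndarray, yy: np.ndarray) -> np.ndarray:
    _, a, x0, y0, sigma = params
    dx = xx - x0
    dy = yy - y0
    e = np.exp(-(dx**2 + dy**2) / (2.0 * sigma**2))
    j = np.empty(params.shape[:0] + (xx.size, 5))
    j[:, 0] = 1.0
    j[:, 1] = e
    j[:, 2] = a * e * dx / sigma**2
    j[:, 3] = a * e * dy / sigma**2
    j[:, 4] = a * e * (dx**2 + dy**2) / sigma**3
    return j


def fit_gaussian(
    frame: np.ndarray,
    candidate_rc: tuple[int, int],
    window_px: int | None = None,
    pixel_size_um: float = 0.05,
    frame_index: int = 0,
    other_candidates_rc: np.ndarray | None = None,
) -> Spot:
    """Fit a symmetric 2D Gaussian on a window around a candidate peak.

    The window (``window_px`` square, odd; by default 2x the expected
    1 um FWHM at the given pixel size) must lie fully inside the frame.
    Window pixels lying closer to another candidate than to this one
    (``other_candidates_rc``) are excluded from the fit so a bright
    neighbor's tail cannot bias the parameters.  Raises
    :class:`SpotFitError` when the optimizer fails or the width collapses
    below 0.5 px (sub-resolution artifact).
    """
    frame = np.asarray(frame, dtype=float)
    if window_px is None:
        window_px = default_window_px(pixel_size_um=pixel_size_um)
    r, c = int(candidate_rc[0]), int(candidate_rc[1])
    hw = window_px // 2
    h, w = frame.shape
    if r - hw < 0 or c - hw < 0 or r + hw >= h or c + hw >= w:
        raise SpotFitError(
            f"window {window_px} px around ({r},{c}) exceeds frame bounds"
        )
    win = frame[r - hw : r + hw + 1, c - hw : c + hw + 1]
    yy, xx = np.mgrid[r - hw : r + hw + 1, c - hw : c + hw + 1].astype(float)
    if other_candidates_rc is not None and len(other_candidates_rc):
        others = np.asarray(other_candidates_rc, dtype=float).reshape(-1, 2)
        d_own = (yy - r) ** 2 + (xx - c) ** 2
        d_other = np.min(
            (yy[..., None] - others[:, 0]) ** 2 + (xx[..., None] - others[:, 1]) ** 2,
            axis=-1,
        )
        keep = d_own <= d_other
        win, yy, xx = win[keep], yy[keep], xx[keep]

    i0 = float(np.median(win))
    a0 = float(win.max() - i0)
    if a0 <= 0:
        raise SpotFitError("no positive contrast in window")
    # second-moment width guess from background-subtracted mass
    mass = np.clip(win - i0, 0, None)
    tot = mass.sum()
    mx = float(np.clip((mass * xx).sum() / tot, c - 3.0, c + 3.0))
    my = float(np.clip((mass * yy).sum() / tot, r - 3.0, r + 3.0))
    var = float((mass * ((xx - mx) ** 2 + (yy - my) ** 2)).sum() / tot) / 2.0
    s0 = float(np.sqrt(max(var, 0.6)))

    xf, yf, zf = xx.ravel(), yy.ravel(), win.ravel()
    res = least_squares(
        lambda p: _gauss_model(p, xf, yf) - zf,
        x0=np.array([i0, a0, mx, my, s0]),
        jac=lambda p: _gauss_jac(p, xf, yf),
        # center constrained near the candidate peak so the fit cannot
        # slide onto a brighter neighbor inside the window
        bounds=(
            [-np.inf, 0.0, c - 3.0, r - 3.0, 0.25],
            [np.inf, np.inf, c + 3.0, r + 3.0, 4.0 * window_px],
        ),
        method="trf",
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
    )
    if not res.success:
        raise SpotFitError(f"fit did not converge at ({r},{c}): {res.message}")
    i0f, af, x0f, y0f, sf = res.x
    if sf < 0.5:
        raise SpotFitError(f"fitted sigma {sf:.3f} px < 0.5 px at ({r},{c})")
    rms = float(np.sqrt(np.mean(res.fun**2)))
    return Spot(
        frame=frame_index,
        x_um=x0f * pixel_size_um,
        y_um=y0f * pixel_size_um,
        diameter_um=FWHM_SIGMA_FACTOR * sf * pixel_size_um,
        intensity=2.0 * np.pi * sf**2 * af * 1.0,  # px^2 * counts (a.u.)
        fit_residual=rms / af,
    )


def locate_spots(
    frame: np.ndarray,
    pixel_size_um: float = 0.05,
    frame_index: int = 0,
    min_contrast: float = 4.0,
    window_px: int | None = None,
) -> pd.DataFrame:
    """Detect and fit all spots in one frame; failed fits are dropped.

    Returns a DataFrame with columns
    ``frame, x_um, y_um, diameter_um, intensity, fit_residual``.
    """
    cands = detect_candidates(frame, min_contrast=min_contrast)
    rows = []
    base_window = (
        window_px if window_px is not None
        else default_window_px(pixel_size_um=pixel_size_um)
    )
    bg = float(np.median(frame)) if frame.size else 0.0
    heights = (
        np.array([frame[r, c] for r, c in cands]) - bg if len(cands) else np.array([])
    )
    for i, rc in enumerate(cands):
        # only comparably bright neighbors mask pixels; a faint noise
        # candidate must not carve pieces out of a real spot's window
        strong = heights >= 0.3 * heights[i]
        strong[i] = False
        others = cands[strong]
        try:
            spot = fit_gaussian(
                frame, rc, window_px=base_window,
                pixel_size_um=pixel_size_um, frame_index=frame_index,
                other_candidates_rc=others,
            )
            # adaptive second pass: a spot larger than assumed needs a
            # window matched to its own FWHM or offset/width/amplitude
            # become degenerate and the intensity estimate noisy
            fwhm_px = spot.diameter_um / pixel_size_um
            want = int(round(2.0 * fwhm_px))
            want += (want + 1) % 2
            if want > base_window:
                spot = fit_gaussian(
                    frame, rc, window_px=want,
                    pixel_size_um=pixel_size_um, frame_index=frame_index,
                    other_candidates_rc=others,
                )
            rows.append(spot)
        except SpotFitError:
            continue
    df = pd.DataFrame(rows, columns=Spot._fields)
    if len(df) > 1:
        # dedupe fits that converged to the same center (< 2 px apart),
        # keeping the better (lower-residual) one
        keep = []
        for i in df.sort_values("fit_residual").index:
            xi, yi = df.at[i, "x_um"], df.at[i, "y_um"]
            if all(
                np.hypot(xi - df.at[k, "x_um"], yi - df.at[k, "y_um"])
                >= 2.0 * pixel_size_um
                for k in keep
            ):
                keep.append(i)
        df = df.loc[sorted(keep)].reset_index(drop=True)
    return df


def locate_stack(
    stack: np.ndarray,
    pixel_size_um: float = 0.05,
    min_contrast: float = 4.0,
    window_px: int | None = None,
) -> pd.DataFrame:
    """Run :func:`locate_spots` on every frame of a stack."""
    frames = [
        locate_spots(
            stack[f], pixel_size_um=pixel_size_um, frame_index=f,
            min_contrast=min_contrast, window_px=window_px,
        )
        for f in range(stack.shape[0])
    ]
    return pd.concat(frames, ignore_index=True)


def filter_by_diameter(
    spots: pd.DataFrame, lo_um: float = 0.5, hi_um: float = 1.5
) -> pd.DataFrame:
    """Keep spots with ``lo_um <= diameter <= hi_um`` (inclusive bounds).

    Order-preserving and idempotent.  The 0.5-1.5 um window selects
    diffraction-resolved granules and rejects both sub-resolution noise
    peaks and large aggregates.
    """
    mask = (spots["diameter_um"] >= lo_um) & (spots["diameter_um"] <= hi_um)
    return spots.loc[mask]
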