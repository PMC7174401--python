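"""End-to-end composition: detection -> tracking -> QC -> drift
correction -> MSD -> viscosity -> rheology -> phenotype.

Each stage writes its table to the output directory and logs counts in
and out of every filter; failures abort with the stage name while
partial outputs are retained.  Reruns with the same config and input are
bit-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from chromorheo._version import __version__ as _version
from chromorheo.config import PipelineConfig
from chromorheo.detection import filter_by_diameter, locate_stack
from chromorheo.msd import compute_msd, estimate_viscosity, fit_anomalous_exponent, fit_diffusion
from chromorheo.phenotype import summarize_nucleus
from chromorheo.rheology import fit_voigt, mason_modulus
from chromorheo.tracking import apply_qc, drift_correct, link_spots

logger = logging.getLogger("chromorheo")

__all__ = ["PipelineError", "PipelineResult", "run_pipeline", "log_spaced_lags"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class PipelineResult:
    spots: pd.DataFrame
    trajectories: pd.DataFrame
    drift: pd.DataFrame | None
    msd: pd.DataFrame
    fits: pd.DataFrame
    spectra: pd.DataFrame
    phenotype: pd.DataFrame
    report: dict


def log_spaced_lags(n_frames: int, max_lag_fraction: float, n_lags: int) -> np.ndarray:
    """Approximately log-spaced integer lags in [1, n_frames*fraction]."""
    kmax = max(int(np.floor(n_frames * max_lag_fraction)), 4)
    lags = np.unique(
        np.round(np.logspace(0, np.log10(kmax), n_lags)).astype(int)
    )
    return lags[lags >= 1]


def _write(df: pd.DataFrame, outdir: Path | None, name: str) -> None:
    if outdir is not None:
        df.to_csv(outdir / name, index=False, float_format="%.10g")


def run_pipeline(
    input_path: str | Path | None = None,
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
    *,
    stack: np.ndarray | None = None,
    trajectories: pd.DataFrame | None = None,
    nucleus_id: str = "nucleus",
) -> PipelineResult:
    """Run the full analysis on an image stack or a pre-linked
    trajectory table.

    ``input_path`` may be a multi-page TIFF (full pipeline) or a
    trajectory CSV with columns ``particle_id, frame, x_um, y_um,
    diameter_um, intensity`` (detection and linking skipped).  In-memory
    ``stack`` / ``trajectories`` arguments bypass file loading.
    """
    cfg = config or PipelineConfig()
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": _version,
        "config_hash": cfg.config_hash,
        "nucleus_id": nucleus_id,
        "stages": {},
    }

    # ---- load ------------------------------------------------------------
    if input_path is not None:
        p = Path(input_path)
        if not p.exists():
            raise PipelineError("load", f"input {p} does not exist")
        if p.suffix.lower() in (".tif", ".tiff"):
            stack = tifffile.imread(p)
        elif p.suffix.lower() == ".csv":
            trajectories = pd.read_csv(p)
        else:
            raise PipelineError("load", f"unsupported input type {p.suffix!r}")
    if stack is None and trajectories is None:
        raise PipelineError("load", "no input provided")

    dt = 1.0 / cfg.acquisition.frame_rate_hz

    # ---- detection + linking --------------------------------------------
    if trajectories is None:
        stack = np.asarray(stack)
        if stack.ndim != 3 or stack.shape[0] == 0 or stack[0].size == 0:
            raise PipelineError("detection", f"empty or non-3D stack {stack.shape}")
        spots = locate_stack(
            stack,
            pixel_size_um=cfg.acquisition.pixel_size_um,
            min_contrast=cfg.detection.min_contrast,
            window_px=cfg.detection.window_px,
        )
        n_det = len(spots)
        spots = filter_by_diameter(
            spots, cfg.detection.diameter_min_um, cfg.detection.diameter_max_um
        ).reset_index(drop=True)
        logger.info("detection: %d spots fitted, %d in diameter band", n_det, len(spots))
        report["stages"]["detection"] = {"n_fitted": n_det, "n_in_band": len(spots)}
        if len(spots) == 0:
            raise PipelineError("detection", "no spots detected")
        _write(spots, out, "spots.csv")
        linked = link_spots(
            stack,
            spots,
            pixel_size_um=cfg.acquisition.pixel_size_um,
            max_disp_um=cfg.tracking.max_disp_um,
            use_descriptors=cfg.tracking.use_descriptors,
        )
        report["stages"]["linking"] = {"n_particles": int(linked["particle_id"].nunique())}
    else:
        required = {"particle_id", "frame", "x_um", "y_um", "diameter_um", "intensity"}
        missing = required - set(trajectories.columns)
        if missing:
            raise PipelineError("load", f"trajectory CSV lacks columns {sorted(missing)}")
        spots = trajectories.copy()
        linked = trajectories.copy()
        report["stages"]["detection"] = "skipped (trajectory input)"

    # ---- QC --------------------------------------------------------------
    qcd = apply_qc(
        linked,
        displacement_mode=cfg.qc.displacement_mode,
        displacement_tol=cfg.qc.displacement_tol,
        size_tol=cfg.qc.size_tol,
        min_length=cfg.qc.min_length,
    )
    accepted = qcd[qcd["qc_status"] == "accepted"]
    n_acc = int(accepted["particle_id"].nunique())
    n_all = int(qcd["particle_id"].nunique())
    logger.info("qc: %d/%d trajectories accepted", n_acc, n_all)
    report["stages"]["qc"] = {"n_trajectories": n_all, "n_accepted": n_acc}
    if n_acc < 2:
        _write(qcd, out, "trajectories.csv")
        raise PipelineError(
            "qc", f"{n_acc} accepted trajectories; drift correction needs >= 2"
        )

    # ---- drift correction ------------------------------------------------
    corrected, drift = drift_correct(accepted, order=cfg.drift.order)
    traj_out = qcd.merge(
        corrected[["particle_id", "frame", "x_corr_um", "y_corr_um"]],
        on=["particle_id", "frame"],
        how="left",
    )
    traj_out.insert(0, "nucleus_id", nucleus_id)
    traj_out["t_s"] = traj_out["frame"] * dt
    _write(traj_out, out, "trajectories.csv")
    _write(drift, out, "drift.csv")

    # ---- MSD, diffusion, viscosity ---------------------------------------
    msd_rows, fit_rows, spec_rows = [], [], []
    for pid, g in corrected.groupby("particle_id"):
        n_frames = len(g)
        lags = log_spaced_lags(n_frames, cfg.msd.max_lag_fraction, cfg.msd.n_lags)
        curve = compute_msd(g, dt, lags=lags)
        msd_rows.append(
            pd.DataFrame(
                {
                    "particle_id": pid,
                    "lag_s": curve.lag_s,
                    "msd_um2": curve.msd_um2,
                    "n_origins": curve.n_origins,
                }
            )
        )
        try:
            dfit = fit_diffusion(curve, max_lag_s=cfg.msd.fit_max_lag_s)
        except ValueError as err:
            logger.warning("particle %s: diffusion fit skipped (%s)", pid, err)
            continue
        radius_um = float(g["diameter_um"].mean() / 2.0)
        visc = estimate_viscosity(
            dfit.d_um2_s,
            radius_um,
            cfg.acquisition.temperature_k,
            dfit.d_stderr_um2_s,
        )
        try:
            alpha_short = fit_anomalous_exponent(
                curve, (0.0, cfg.msd.fit_max_lag_s)
            )
        except ValueError:
            alpha_short = np.nan
        try:
            alpha_long = fit_anomalous_exponent(
                curve, (cfg.msd.fit_max_lag_s, np.inf)
            )
        except ValueError:
            alpha_long = np.nan
        row = {
            "particle_id": pid,
            "n_frames": n_frames,
            "d_eff_um2_s": dfit.d_um2_s,
            "d_stderr_um2_s": dfit.d_stderr_um2_s,
            "alpha_short": alpha_short,
            "alpha_long": alpha_long,
            "radius_um": radius_um,
            "diameter_um": 2 * radius_um,
            "temperature_k": cfg.acquisition.temperature_k,
            "eta_app_pa_s": visc.eta_app_pa_s,
            "eta_unc_pa_s": visc.uncertainty_pa_s,
            "intensity": float(g["intensity"].mean()),
            "g_prime_pa": np.nan,
            "eta_voigt_pa_s": np.nan,
        }
        # ---- rheology -----------------------------------------------------
        try:
            spec = mason_modulus(
                curve,
                radius_um,
                cfg.acquisition.temperature_k,
                slope_window=cfg.rheology.slope_window,
            )
            spec_rows.append(
                pd.DataFrame(
                    {
                        "particle_id": pid,
                        "omega_rad_s": spec.omega_rad_s,
                        "gd_pa": spec.gd_pa,
                        "delta_rad": spec.delta_rad,
                        "gp_pa": spec.gp_pa,
                        "gpp_pa": spec.gpp_pa,
                        "eta_pa_s": spec.eta_pa_s,
                        "masked": spec.masked,
                    }
                )
            )
            vf = fit_voigt(spec, flatness_tol=cfg.rheology.flatness_tol)
            row["g_prime_pa"] = vf.g_prime_pa if vf.plateau_found else np.nan
            row["eta_voigt_pa_s"] = vf.eta_pa_s
        except ValueError as err:
            logger.warning("particle %s: rheology skipped (%s)", pid, err)
        fit_rows.append(row)

    msd_df = pd.concat(msd_rows, ignore_index=True) if msd_rows else pd.DataFrame()
    fits_df = pd.DataFrame(fit_rows)
    spectra_df = (
        pd.concat(spec_rows, ignore_index=True) if spec_rows else pd.DataFrame()
    )
    _write(msd_df, out, "msd.csv")
    _write(fits_df, out, "fits.csv")
    _write(spectra_df, out, "spectra.csv")
    if len(fits_df) < 2:
        raise PipelineError("msd", "fewer than 2 particles with diffusion fits")

    # ---- phenotype --------------------------------------------------------
    pheno = summarize_nucleus(
        fits_df,
        nucleus_id=nucleus_id,
        min_particles=cfg.phenotype.min_particles,
        strict=cfg.phenotype.strict,
    )
    pheno_df = pd.DataFrame([asdict(pheno)])
    _write(pheno_df, out, "phenotype.csv")
    report["stages"]["phenotype"] = asdict(pheno)
    if out is not None:
        (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return PipelineResult(
        spots=spots,
        trajectories=traj_out,
        drift=drift,
        msd=msd_df,
        fits=fits_df,
        spectra=spectra_df,
        phenotype=pheno_df,
        report=report,
    )
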