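"""Per-nucleus mechanical phenotypes and non-parametric group comparison.

The phenotype of a nucleus is the average over its accepted granules
(normally at least 10) of the apparent viscosity, plus an optical-density
descriptor (background-corrected integrated spot intensity per unit spot
area) and the mean optical radius.  Groups of nuclei are compared with a
two-sided Mann-Whitney U test (2 groups) or Kruskal-Wallis H test
(3 or more); raw p-values are reported, with optional Holm correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "NucleusPhenotype",
    "GroupComparison",
    "summarize_nucleus",
    "compare_groups",
]


@dataclass
class NucleusPhenotype:
    """Per-nucleus summary over accepted particles.

    ``optical_density`` is total integrated spot intensity divided by
    total spot area (pi (D/2)^2 summed), in a.u./um^2.  ``area_um2`` is
    the nuclear area from a segmentation mask when one is supplied.
    """

    nucleus_id: str
    n_particles: int
    eta_mean_pa_s: float
    eta_sd_pa_s: float
    optical_density: float
    radius_um: float
    area_um2: float | None = None


@dataclass
class GroupComparison:
    test: str
    statistic: float
    p_value: float
    groups: dict[str, np.ndarray]
    significant: bool


def summarize_nucleus(
    particle_results: pd.DataFrame,
    nucleus_id: str = "nucleus",
    min_particles: int = 10,
    strict: bool = False,
    area_um2: float | None = None,
) -> NucleusPhenotype:
    """Aggregate per-particle fits of one nucleus into a phenotype.

    ``particle_results`` needs columns ``particle_id, eta_app_pa_s,
    diameter_um, intensity``; infinite-viscosity particles are excluded
    from the eta average.  Fewer than 2 particles is a hard error (drift
    correction is undefined upstream); fewer than ``min_particles``
    warns, or raises when ``strict``.  Duplicate particle ids are
    rejected.
    """
    if particle_results["particle_id"].duplicated().any():
        raise ValueError("duplicate particle_id rows in nucleus table")
    n = len(particle_results)
    if n < 2:
        raise ValueError(f"nucleus {nucleus_id!r} has {n} accepted particles; need >= 2")
    if n < min_particles:
        msg = (
            f"nucleus {nucleus_id!r} has only {n} accepted particles "
            f"(phenotype validity threshold {min_particles})"
        )
        if strict:
            raise ValueError(msg)
        warnings.warn(msg)
    eta = particle_results["eta_app_pa_s"].to_numpy(dtype=float)
    finite = np.isfinite(eta)
    if finite.sum() < 2:
        raise ValueError("fewer than 2 finite viscosity estimates")
    diam = particle_results["diameter_um"].to_numpy(dtype=float)
    inten = particle_results["intensity"].to_numpy(dtype=float)
    area = np.pi * (diam / 2.0) ** 2
    return NucleusPhenotype(
        nucleus_id=nucleus_id,
        n_particles=int(n),
        eta_mean_pa_s=float(np.mean(eta[finite])),
        eta_sd_pa_s=float(np.std(eta[finite], ddof=1)),
        optical_density=float(inten.sum() / area.sum()),
        radius_um=float(np.mean(diam) / 2.0),
        area_um2=area_um2,
    )


def compare_groups(
    groups: dict[str, np.ndarray],
    test: str = "auto",
    alpha: float = 0.05,
    min_group_size: int = 3,
) -> GroupComparison:
    """Compare a phenotype metric between groups of nuclei.

    Two groups -> two-sided Mann-Whitney U (exact where sample sizes
    allow); three or more -> Kruskal-Wallis H.  Ties are handled by
    midranks; degenerate all-equal data returns p = 1.  The significance
    label uses ``alpha`` but never filters data.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if len(v) < min_group_size:
            raise ValueError(f"group {k!r} has {len(v)} nuclei; need >= {min_group_size}")
    values = list(arrays.values())
    pooled = np.concatenate(values)
    if np.all(pooled == pooled[0]):
        name = "mann-whitney" if len(groups) == 2 else "kruskal-wallis"
        return GroupComparison(name, np.nan, 1.0, arrays, False)
    if test == "auto":
        test = "mann-whitney" if len(groups) == 2 else "kruskal-wallis"
    if test == "mann-whitney":
        if len(groups) != 2:
            raise ValueError("Mann-Whitney requires exactly 2 groups")
        stat, p = stats.mannwhitneyu(values[0], values[1], alternative="two-sided")
    elif test == "kruskal-wallis":
        stat, p = stats.kruskal(*values)
    else:
        raise ValueError(f"unknown test {test!r}")
    return GroupComparison(test, float(stat), float(p), arrays, bool(p < alpha))


def holm_correction(p_values: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values (optional; raw p-values are the
    default report)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    n = len(p)
    adj = np.empty(n)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (n - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj
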