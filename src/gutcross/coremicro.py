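"""Core-microbiome analysis: ubiquity curves, core surfaces, and the AWKS statistic.

Ubiquity of a taxon at abundance threshold a is the fraction of a cohort's
samples carrying it at relative abundance >= a; sweeping a log-spaced
threshold grid gives a non-increasing ubiquity curve per taxon. The core
surface reports, for each (abundance, ubiquity) grid cell, the fraction of
taxa whose ubiquity at that abundance clears the ubiquity cut. Taxa are
classed into major/minor cores by reference thresholds, and two cohorts'
ubiquity curves are compared per taxon with an abundance-weighted
Kolmogorov-Smirnov-style statistic

    D = sum_k a_k * |U_A(a_k) - U_B(a_k)| / sum_k a_k,

a weighted L1 gap over the grid in [0, 1] (higher-abundance disagreements
weigh more); p by cohort-label permutation. A sup-norm (classic KS) variant
is available via ``weighted=False``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import TestResult


def default_grid(profiles: pd.DataFrame | None = None, n: int = 30) -> np.ndarray:
    """Descending-use log-spaced abundance grid from 1e-5 to the max observed relabund."""
    top = 1.0 if profiles is None else float(profiles.to_numpy().max())
    top = max(top, 2e-5)
    return np.geomspace(1e-5, top, n)


def ubiquity_curve(
    profiles: pd.DataFrame, cohort: list, taxon, grid: np.ndarray | None = None
) -> pd.Series:
    """U(a) = fraction of cohort samples with the taxon's relabund >= a."""
    if grid is None:
        grid = default_grid(profiles)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty abundance grid")
    if len(cohort) < 1:
        raise ValueError("cohort needs >= 1 sample")
    v = profiles.loc[taxon, cohort].to_numpy(dtype=float)
    U = (v[None, :] >= grid[:, None]).mean(axis=1)
    return pd.Series(U, index=grid, name=str(taxon))


def ubiquity_matrix(profiles: pd.DataFrame, cohort: list, grid: np.ndarray) -> np.ndarray:
    """Taxa x grid ubiquity values for a whole cohort."""
    V = profiles[cohort].to_numpy(dtype=float)
    return (V[:, None, :] >= grid[None, :, None]).mean(axis=2)


def core_fraction_surface(
    profiles: pd.DataFrame,
    cohort: list,
    abundance_grid: np.ndarray | None = None,
    ubiquity_grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Fraction of taxa with U(a) >= u for every (a, u) cell; non-increasing in both."""
    if abundance_grid is None:
        abundance_grid = default_grid(profiles)
    if ubiquity_grid is None:
        ubiquity_grid = np.linspace(0.0, 1.0, 11)
    abundance_grid = np.asarray(abundance_grid, dtype=float)
    ubiquity_grid = np.asarray(ubiquity_grid, dtype=float)
    if abundance_grid.size == 0 or ubiquity_grid.size == 0:
        raise ValueError("empty grid")
    U = ubiquity_matrix(profiles, cohort, abundance_grid)  # taxa x A
    surface = (U[:, :, None] >= ubiquity_grid[None, None, :] - 1e-12).mean(axis=0)
    return pd.DataFrame(surface, index=abundance_grid, columns=ubiquity_grid)


@dataclass
class CoreThresholds:
    major_abundance: float = 1e-3
    major_ubiquity: float = 0.75
    minor_abundance: float = 1e-4
    minor_ubiquity: float = 0.5


def classify_cores(
    profiles: pd.DataFrame, cohort: list, thresholds: CoreThresholds | None = None
) -> pd.DataFrame:
    """Per-taxon abundance/variability/ubiquity plot data with major/minor core classes.

    major: ubiquity at the major reference abundance >= its cut; minor: not
    major but ubiquitous at trace level; else none. Variability is the
    coefficient of variation of relative abundance across cohort samples.
    """
    th = thresholds or CoreThresholds()
    V = profiles[cohort].to_numpy(dtype=float)
    mean = V.mean(axis=1)
    sd = V.std(axis=1, ddof=1) if V.shape[1] > 1 else np.zeros_like(mean)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean > 0, sd / mean, np.nan)
    u_major = (V >= th.major_abundance).mean(axis=1)
    u_minor = (V >= th.minor_abundance).mean(axis=1)
    major = u_major >= th.major_ubiquity
    minor = ~major & (u_minor >= th.minor_ubiquity)
    core_class = np.where(major, "major", np.where(minor, "minor", "none"))
    return pd.DataFrame(
        {
            "mean_abundance": mean,
            "variability": cv,
            "ubiquity_major_ref": u_major,
            "ubiquity_minor_ref": u_minor,
            "core_class": core_class,
        },
        index=profiles.index,
    )


def awks_test(
    profiles: pd.DataFrame,
    cohort_a: list,
    cohort_b: list,
    taxon,
    n_perm: int = 1000,
    grid: np.ndarray | None = None,
    weighted: bool = True,
    seed: int = 0,
) -> TestResult:
    """Abundance-weighted KS comparison of two cohorts' ubiquity curves for one taxon."""
    if set(cohort_a) & set(cohort_b):
        raise ValueError("cohorts overlap")
    if len(cohort_a) < 3 or len(cohort_b) < 3:
        raise ValueError("both cohorts need >= 3 samples")
    if grid is None:
        grid = default_grid(profiles)
    grid = np.asarray(grid, dtype=float)
    va = profiles.loc[taxon, cohort_a].to_numpy(dtype=float)
    vb = profiles.loc[taxon, cohort_b].to_numpy(dtype=float)
    pooled = np.concatenate([va, vb])
    na = va.size
    I = pooled[None, :] >= grid[:, None]  # grid x samples
    w = grid if weighted else np.ones_like(grid)

    def dstat(mask_a: np.ndarray) -> np.ndarray:
        # mask_a: samples x P indicator of cohort-A membership
        Ua = (I.astype(float) @ mask_a) / na
        Ub = (I.astype(float) @ (1.0 - mask_a)) / (pooled.size - na)
        return (w @ np.abs(Ua - Ub)) / w.sum()

    obs_mask = np.zeros((pooled.size, 1))
    obs_mask[:na, 0] = 1.0
    obs = float(dstat(obs_mask)[0])
    rng = np.random.default_rng(seed)
    masks = np.zeros((pooled.size, n_perm))
    for j in range(n_perm):
        masks[rng.permutation(pooled.size)[:na], j] = 1.0
    perm = dstat(masks)
    p = (1.0 + np.sum(perm >= obs - 1e-12)) / (1.0 + n_perm)
    return TestResult("awks", obs, float(p), n_perm)
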