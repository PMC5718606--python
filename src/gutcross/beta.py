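"""Depth normalization, beta-diversity distances, UniFrac, and permutation tests.

Distances follow the mothur conventions the field's crossover studies report:
Bray-Curtis, Jaccard (classical, membership only), Yue & Clayton's ThetaYC
dissimilarity, and Morisita-Horn. Group tests are distance-based permutation
tests: PERMANOVA (pseudo-F on squared distances), AMOVA (Excoffier-style
variance-component ratio), HOMOVA (Bartlett-style homogeneity of within-group
dispersion), and the Mantel test for matrix correlation. Permutation p-values
use the (1 + count)/(1 + N) estimator and are never zero; multiple-testing
control is Benjamini-Hochberg.

Labels are permuted freely by default. The crossover layout pairs samples
within participants; a within-participant-constrained scheme is available via
the ``strata`` argument but off by default.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import beta_diversity
from statsmodels.stats.multitest import multipletests

from ._util import TestResult

METRICS = ("braycurtis", "jaccard", "thetayc", "morisitahorn")


def rarefy_counts(table: pd.DataFrame, depth: int, seed: int = 0) -> pd.DataFrame:
    """Subsample every column (sample) without replacement to exactly ``depth`` reads.

    Samples with fewer reads than ``depth`` are dropped with a warning.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    sums = table.sum(axis=0)
    keep = sums[sums >= depth].index
    if len(keep) < table.shape[1]:
        warnings.warn(f"dropping {table.shape[1] - len(keep)} sample(s) below depth {depth}")
    out = {}
    for s in keep:
        col = table[s].to_numpy().astype(np.int64)
        if col.sum() == depth:
            out[s] = col
        else:
            out[s] = rng.multivariate_hypergeometric(col, depth)
    return pd.DataFrame(out, index=table.index)


def _relabund(table: pd.DataFrame) -> np.ndarray:
    """samples x taxa relative abundances; errors on zero-total samples."""
    X = table.to_numpy(dtype=float).T
    totals = X.sum(axis=1)
    if np.any(totals <= 0):
        raise ValueError("sample(s) with zero total abundance")
    return X / totals[:, None]


def pairwise_distance(table: pd.DataFrame, metric: str) -> DistanceMatrix:
    """Pairwise dissimilarity matrix between samples (columns) of a count table."""
    if table.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    ids = [str(c) for c in table.columns]
    if metric == "braycurtis":
        X = table.to_numpy(dtype=float).T
        if np.any(X.sum(axis=1) <= 0):
            raise ValueError("sample(s) with zero total abundance")
        d = squareform(pdist(X, metric="braycurtis"))
    elif metric == "jaccard":
        X = table.to_numpy(dtype=float).T
        if np.any(X.sum(axis=1) <= 0):
            raise ValueError("sample(s) with zero total abundance")
        d = squareform(pdist(X > 0, metric="jaccard"))
    elif metric in ("thetayc", "morisitahorn"):
        P = _relabund(table)
        cross = P @ P.T
        sq = np.sum(P**2, axis=1)
        if metric == "thetayc":
            denom = sq[:, None] + sq[None, :] - cross
            d = 1.0 - cross / denom
        else:
            d = 1.0 - 2.0 * cross / (sq[:, None] + sq[None, :])
        np.fill_diagonal(d, 0.0)
        d = np.clip((d + d.T) / 2.0, 0.0, 1.0)
    else:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    return DistanceMatrix(d, ids)


def unifrac(
    table: pd.DataFrame, tree: str | TreeNode, weighted: bool = False
) -> DistanceMatrix:
    """Unweighted or weighted (normalized) UniFrac between samples.

    All table taxa must be leaves of the tree; the weighted variant is the
    branch-length-weighted L1 difference of subtree proportions, normalized so
    it is bounded by 1.
    """
    if isinstance(tree, str):
        tree = TreeNode.read([tree])
    tips = {t.name for t in tree.tips()}
    missing = [t for t in table.index if t not in tips]
    if missing:
        raise ValueError(f"taxa missing from tree: {missing[:5]}")
    counts = table.to_numpy(dtype=float).T
    ids = [str(c) for c in table.columns]
    metric = "weighted_unifrac" if weighted else "unweighted_unifrac"
    kwargs = {"normalized": True} if weighted else {}
    return beta_diversity(
        metric, counts, ids=ids, taxa=list(table.index), tree=tree, validate=True, **kwargs
    )


def _group_codes(groups) -> tuple[np.ndarray, np.ndarray]:
    codes, uniques = pd.factorize(pd.Series(list(groups)))
    return codes.astype(np.int64), np.bincount(codes)


def _ss_components(
    d2: np.ndarray, codes: np.ndarray, n_groups: int
) -> tuple[float, np.ndarray]:
    """Total SS and per-group within SS from a squared-distance matrix."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = np.empty(n_groups)
    for g in range(n_groups):
        m = codes == g
        ng = int(m.sum())
        ss_within[g] = d2[np.ix_(m, m)].sum() / (2.0 * ng)
    return float(ss_total), ss_within


def _permutation(n: int, rng, strata: np.ndarray | None) -> np.ndarray:
    """A free permutation of 0..n-1, or one constrained within strata."""
    if strata is None:
        return rng.permutation(n)
    order = np.arange(n)
    for s in np.unique(strata):
        idx = np.flatnonzero(strata == s)
        order[idx] = idx[rng.permutation(len(idx))]
    return order


def _permuted_within_ss(
    d2: np.ndarray, codes: np.ndarray, n_groups: int, n_perm: int, rng,
    strata: np.ndarray | None = None,
) -> np.ndarray:
    """Within-group SS per group for n_perm label permutations (n_perm x K)."""
    n = d2.shape[0]
    perms = np.empty((n_perm, n), dtype=np.int64)
    for i in range(n_perm):
        perms[i] = codes[_permutation(n, rng, strata)]
    ss = np.empty((n_perm, n_groups))
    for g in range(n_groups):
        M = (perms == g).astype(float)
        ng = M[0].sum()
        ss[:, g] = np.einsum("pi,pi->p", M @ d2, M) / (2.0 * ng)
    return ss


def _validate_groups(dm: DistanceMatrix, groups) -> tuple[np.ndarray, np.ndarray]:
    codes, sizes = _group_codes(groups)
    if len(codes) != dm.shape[0]:
        raise ValueError("groups length does not match distance matrix")
    if len(sizes) < 2:
        raise ValueError("need >= 2 groups")
    if (sizes < 2).any():
        raise ValueError("every group needs >= 2 samples")
    return codes, sizes


def permanova(
    dm: DistanceMatrix, groups, n_perm: int = 10_000, seed: int = 0, strata=None
) -> TestResult:
    """Non-parametric MANOVA: pseudo-F from among/within sums of squared distances."""
    codes, sizes = _validate_groups(dm, groups)
    k, n = len(sizes), dm.shape[0]
    d2 = dm.data**2
    ss_total, ss_within_g = _ss_components(d2, codes, k)
    ss_w = ss_within_g.sum()
    f_obs = ((ss_total - ss_w) / (k - 1)) / (ss_w / (n - k))
    rng = np.random.default_rng(seed)
    strata = None if strata is None else np.asarray(pd.factorize(pd.Series(list(strata)))[0])
    ss_w_perm = _permuted_within_ss(d2, codes, k, n_perm, rng, strata).sum(axis=1)
    f_perm = ((ss_total - ss_w_perm) / (k - 1)) / (ss_w_perm / (n - k))
    p = (1.0 + np.sum(f_perm >= f_obs - 1e-12)) / (1.0 + n_perm)
    return TestResult("permanova", float(f_obs), float(p), n_perm)


def amova(
    dm: DistanceMatrix, groups, n_perm: int = 10_000, seed: int = 0, strata=None
) -> TestResult:
    """Analysis of molecular variance on squared distances.

    Statistic is the variance-component ratio sigma2_among / sigma2_within with
    sigma2_among = (MS_among - MS_within)/n0 and n0 the Excoffier effective
    group size; the permutation distribution permutes labels freely.
    """
    codes, sizes = _validate_groups(dm, groups)
    k, n = len(sizes), dm.shape[0]
    d2 = dm.data**2
    n0 = (n - np.sum(sizes**2) / n) / (k - 1)
    ss_total, ss_within_g = _ss_components(d2, codes, k)

    def stat(ss_w: np.ndarray) -> np.ndarray:
        ms_a = (ss_total - ss_w) / (k - 1)
        ms_w = ss_w / (n - k)
        return ((ms_a - ms_w) / n0) / ms_w

    obs = float(stat(np.asarray(ss_within_g.sum())))
    rng = np.random.default_rng(seed)
    strata = None if strata is None else np.asarray(pd.factorize(pd.Series(list(strata)))[0])
    perm = stat(_permuted_within_ss(d2, codes, k, n_perm, rng, strata).sum(axis=1))
    p = (1.0 + np.sum(perm >= obs - 1e-12)) / (1.0 + n_perm)
    return TestResult("amova", obs, float(p), n_perm)


def homova(
    dm: DistanceMatrix, groups, n_perm: int = 10_000, seed: int = 0, strata=None
) -> TestResult:
    """Homogeneity of molecular variance: Bartlett-style statistic on within-group
    dispersions (mean squared within-group distance); B >= 0, larger = more
    heterogeneous dispersion."""
    codes, sizes = _validate_groups(dm, groups)
    k, n = len(sizes), dm.shape[0]
    d2 = dm.data**2

    def bartlett(ss_within_g: np.ndarray) -> np.ndarray:
        disp = ss_within_g / (sizes - 1)
        pooled = ss_within_g.sum(axis=-1) / (n - k)
        with np.errstate(divide="ignore"):
            return (n - k) * np.log(pooled) - np.sum((sizes - 1) * np.log(disp), axis=-1)

    _, ss_within_g = _ss_components(d2, codes, k)
    obs = float(bartlett(ss_within_g))
    rng = np.random.default_rng(seed)
    strata = None if strata is None else np.asarray(pd.factorize(pd.Series(list(strata)))[0])
    perm = bartlett(_permuted_within_ss(d2, codes, k, n_perm, rng, strata))
    p = (1.0 + np.sum(perm >= obs - 1e-12)) / (1.0 + n_perm)
    return TestResult("homova", obs, float(p), n_perm)


def mantel(
    dm1: DistanceMatrix, dm2: DistanceMatrix, n_perm: int = 9_999, seed: int = 0
) -> TestResult:
    """Mantel correlation between two distance matrices over the same samples.

    Pearson r over strictly-upper-triangle entries; one matrix's joint
    row/column order is permuted; one-sided p for positive association.
    The squared correlation is reported in ``extra['r_squared']``.
    """
    if list(dm1.ids) != list(dm2.ids):
        raise ValueError("distance matrices must share labels in the same order")
    n = dm1.shape[0]
    iu = np.triu_indices(n, k=1)
    x = dm1.data[iu]
    y = dm2.data[iu]
    xc = (x - x.mean()) / x.std()
    yc = (y - y.mean()) / y.std()
    r_obs = float(np.mean(xc * yc))
    rng = np.random.default_rng(seed)
    D1 = dm1.data
    perm_r = np.empty(n_perm)
    for i in range(n_perm):
        order = rng.permutation(n)
        xp = D1[np.ix_(order, order)][iu]
        xp = (xp - xp.mean()) / xp.std()
        perm_r[i] = np.mean(xp * yc)
    p = (1.0 + np.sum(perm_r >= r_obs - 1e-12)) / (1.0 + n_perm)
    return TestResult("mantel", r_obs, float(p), n_perm, extra={"r_squared": r_obs**2})


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, order-preserving)."""
    p = np.asarray(pd.Series(p_values).to_numpy(), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
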