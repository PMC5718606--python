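"""Step-down variable screening and three-matrix variation partitioning.

Community counts are Hellinger-transformed (square root of relative
abundance) and explained by redundancy analysis (RDA = multivariate linear
regression; R^2 is the fraction of total community variance captured by the
fitted values, adjusted with the Ezekiel correction). Each explanatory matrix
is first screened: every variable is tested marginally by single-predictor
RDA with a permutation p, non-significant variables are dropped, and
co-correlated survivors (|r| above a cutoff) are pruned down to one
representative. The adjusted R^2 of all seven non-empty subsets of
{X1, X2, X3} then yields, by inclusion-exclusion, the pure and shared
fractions of community variance per matrix plus the unexplained remainder;
the eight numbers sum to 1 exactly. Negative adjusted fractions are reported
as-is (standard behaviour for adjusted partitions), never clipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd


def hellinger(counts: pd.DataFrame) -> pd.DataFrame:
    """Hellinger transform of a taxa x samples count table -> samples x taxa."""
    X = counts.to_numpy(dtype=float).T
    totals = X.sum(axis=1, keepdims=True)
    if np.any(totals <= 0):
        raise ValueError("zero-total sample(s)")
    return pd.DataFrame(np.sqrt(X / totals), index=counts.columns, columns=counts.index)


def _center(M: np.ndarray) -> np.ndarray:
    return M - M.mean(axis=0, keepdims=True)


def rda_r2(Y: np.ndarray, X: np.ndarray) -> tuple[float, int]:
    """Unadjusted RDA R^2 of community Y on predictors X, and the predictor rank."""
    Yc = _center(np.asarray(Y, dtype=float))
    ss_tot = float(np.sum(Yc**2))
    if X.shape[1] == 0:
        return 0.0, 0
    Xc = _center(np.asarray(X, dtype=float))
    coef, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
    fitted = Xc @ coef
    m = int(np.linalg.matrix_rank(Xc))
    return float(np.sum(fitted**2) / ss_tot), m


def adjusted_r2(r2: float, n: int, m: int) -> float:
    """Ezekiel-corrected R^2 for n samples and m (rank) predictors."""
    if m == 0:
        return 0.0
    if n - m - 1 <= 0:
        raise ValueError("too many predictors for adjusted R^2")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)


def _marginal_r2_perms(
    Yc: np.ndarray, x: np.ndarray, n_perm: int, rng
) -> tuple[float, np.ndarray]:
    """R^2 of a single standardized predictor and its permutation distribution."""
    n = x.size
    ss_tot = float(np.sum(Yc**2))
    xc = x - x.mean()
    norm = np.linalg.norm(xc)
    xc = xc / norm
    obs = float(np.sum((xc @ Yc) ** 2) / ss_tot)
    idx = np.argsort(rng.random((n_perm, n)), axis=1)
    Xp = xc[idx]
    perm = np.sum((Xp @ Yc) ** 2, axis=1) / ss_tot
    return obs, perm


def stepdown_screen(
    community: pd.DataFrame,
    matrix: pd.DataFrame,
    n_perm: int = 5000,
    alpha: float = 0.05,
    r_max: float = 0.8,
    seed: int = 0,
    probe: bool = False,
) -> list[str]:
    """Step-down screen of one explanatory matrix against the community.

    ``community`` is a Hellinger-transformed samples x taxa frame aligned to
    ``matrix`` rows. Stage 1 drops variables whose marginal single-predictor
    RDA permutation p >= alpha (or, in ``probe`` mode, whose marginal R^2
    does not exceed the 95th percentile of a shuffled probe variable's R^2
    distribution). Stage 2 prunes co-correlated survivors: while any retained
    pair has |Pearson r| > r_max, the member with the larger mean absolute
    correlation to the remaining retained variables is dropped.
    """
    if list(community.index) != list(matrix.index):
        matrix = matrix.reindex(community.index)
        if matrix.isna().any().any():
            raise ValueError("matrix not aligned to community samples")
    rng = np.random.default_rng(seed)
    Yc = _center(community.to_numpy(dtype=float))
    retained: list[str] = []
    probe_cut = None
    if probe:
        x = rng.permutation(matrix.iloc[:, 0].to_numpy(dtype=float))
        _, perm = _marginal_r2_perms(Yc, x, n_perm, rng)
        probe_cut = float(np.quantile(perm, 0.95))
    for col in matrix.columns:
        x = matrix[col].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            warnings.warn(f"dropping constant variable {col!r}")
            continue
        obs, perm = _marginal_r2_perms(Yc, x, n_perm, rng)
        if probe:
            if obs > probe_cut:
                retained.append(col)
        else:
            p = (1.0 + np.sum(perm >= obs - 1e-15)) / (1.0 + n_perm)
            if p < alpha:
                retained.append(col)
    # co-correlation pruning
    while len(retained) > 1:
        R = np.abs(np.corrcoef(matrix[retained].to_numpy(dtype=float), rowvar=False))
        np.fill_diagonal(R, 0.0)
        i, j = np.unravel_index(np.argmax(R), R.shape)
        if R[i, j] <= r_max:
            break
        drop = i if R[i].mean() >= R[j].mean() else j
        retained.pop(drop)
    return retained


@dataclass
class PartitionResult:
    """Pure/shared/unexplained fractions of community variance for three matrices."""

    fractions: dict
    unexplained: float
    adj_r2: dict
    p_values: dict = field(default_factory=dict)
    retained: dict = field(default_factory=dict)

    def summary(self) -> pd.Series:
        out = dict(self.fractions)
        out["unexplained"] = self.unexplained
        return pd.Series(out)


def partition_variation(
    community: pd.DataFrame,
    X1: pd.DataFrame,
    X2: pd.DataFrame,
    X3: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
    names: tuple[str, str, str] = ("X1", "X2", "X3"),
) -> PartitionResult:
    """Three-way variation partitioning by adjusted RDA R^2 and inclusion-exclusion.

    community: Hellinger-transformed samples x taxa frame. X1..X3: screened
    explanatory matrices on the same samples (zero-column matrices reduce the
    result to a two-way partition). Marginal matrix significance is a
    permutation test of the single-matrix RDA R^2 under row shuffling.
    """
    mats = [X1, X2, X3]
    n = len(community)
    for X in mats:
        if len(X) != n:
            raise ValueError("explanatory matrices must share the community sample set")
    total_vars = sum(X.shape[1] for X in mats)
    if total_vars > n - 2:
        raise ValueError(
            f"{total_vars} retained variables for {n} samples; screen more aggressively"
        )
    Y = community.to_numpy(dtype=float)

    def adj(subset: tuple[int, ...]) -> float:
        X = np.concatenate([mats[i].to_numpy(dtype=float) for i in subset], axis=1)
        r2, m = rda_r2(Y, X)
        return adjusted_r2(r2, n, m)

    u: dict[tuple[int, ...], float] = {(): 0.0}
    for r in (1, 2, 3):
        for subset in combinations(range(3), r):
            u[subset] = adj(subset)

    a = u[(0, 1, 2)] - u[(1, 2)]
    b = u[(0, 1, 2)] - u[(0, 2)]
    c = u[(0, 1, 2)] - u[(0, 1)]
    d = u[(0, 2)] + u[(1, 2)] - u[(0, 1, 2)] - u[(2,)]  # 1&2 not 3
    e = u[(0, 1)] + u[(0, 2)] - u[(0, 1, 2)] - u[(0,)]  # 2&3 not 1
    f = u[(0, 1)] + u[(1, 2)] - u[(0, 1, 2)] - u[(1,)]  # 1&3 not 2
    g = u[(0, 1, 2)] - (a + b + c + d + e + f)
    n1, n2, n3 = names
    fractions = {
        f"pure_{n1}": a,
        f"pure_{n2}": b,
        f"pure_{n3}": c,
        f"shared_{n1}_{n2}": d,
        f"shared_{n2}_{n3}": e,
        f"shared_{n1}_{n3}": f,
        f"shared_{n1}_{n2}_{n3}": g,
    }
    unexplained = 1.0 - u[(0, 1, 2)]

    rng = np.random.default_rng(seed)
    p_values = {}
    for i, name in enumerate(names):
        X = mats[i].to_numpy(dtype=float)
        if X.shape[1] == 0 or n_perm < 1:
            p_values[name] = float("nan")
            continue
        obs, _ = rda_r2(Y, X)
        count = 0
        for _ in range(n_perm):
            perm_r2, _ = rda_r2(Y, X[rng.permutation(n)])
            count += perm_r2 >= obs - 1e-15
        p_values[name] = (1.0 + count) / (1.0 + n_perm)

    adj_named = {"+".join(names[i] for i in k): v for k, v in u.items() if k}
    return PartitionResult(
        fractions=fractions, unexplained=unexplained, adj_r2=adj_named, p_values=p_values
    )
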