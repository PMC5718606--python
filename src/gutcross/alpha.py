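"""The 13-index alpha-diversity suite.

Applies to any non-negative abundance vector: integer counts (microbial
genus/OTU tables) or real-valued compositions (HPLC fingerprint profiles).
Shannon uses the natural logarithm. Indices that require genuine individual
counts (Brillouin, Chao-1, Fisher alpha, and the raw Individuals total) are
refused in profile mode. Degenerate edge cases (S = 1 or N = 1) return NaN
for Margalef and Equitability_J rather than infinities.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import gammaln

COUNT_ONLY = {"Individuals", "Brillouin", "Fisher_alpha", "Chao1"}

INDEX_NAMES = [
    "Taxa_S",
    "Individuals",
    "Dominance_D",
    "Simpson_1-D",
    "Shannon_H",
    "Evenness",
    "Brillouin",
    "Menhinick",
    "Margalef",
    "Equitability_J",
    "Fisher_alpha",
    "Berger-Parker",
    "Chao1",
]


def fisher_alpha_solve(S: float, N: float, tol: float = 1e-12) -> float:
    """Solve S = alpha * ln(1 + N/alpha) for Fisher's log-series alpha.

    Bracketed bisection followed by Newton polish; the residual of the
    returned root is below 1e-10. Requires 0 < S < N (S >= N has no finite
    positive root).
    """
    if S <= 0:
        raise ValueError("S must be positive")
    if S >= N:
        raise ValueError("Fisher alpha undefined for S >= N")

    def f(alpha: float) -> float:
        return alpha * np.log1p(N / alpha) - S

    lo, hi = 1e-12, 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e12:  # pragma: no cover - unreachable for S < N
            raise RuntimeError("failed to bracket Fisher alpha")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < max(1e-15, tol * mid):
            break
    alpha = 0.5 * (lo + hi)
    # Newton polish: f'(alpha) = ln(1 + N/a) - N/(a + N)
    for _ in range(50):
        fa = f(alpha)
        if abs(fa) < 1e-11:
            break
        deriv = np.log1p(N / alpha) - N / (alpha + N)
        step = fa / deriv
        if not np.isfinite(step):
            break
        alpha -= step
    return float(alpha)


def alpha_profile(values, mode: str = "counts") -> pd.Series:
    """All 13 indices for one abundance vector.

    mode='counts' expects non-negative integers; mode='profile' accepts any
    non-negative reals but reports NaN-free values only for the
    relative-abundance-based indices and raises if a count-only index would
    be fabricated (they are returned as NaN).
    """
    v = np.asarray(pd.Series(values).to_numpy(), dtype=float)
    if v.size == 0:
        raise ValueError("empty abundance vector")
    if (v < 0).any():
        raise ValueError("negative abundances")
    N = float(v.sum())
    if N <= 0:
        raise ValueError("vector sums to zero")
    if mode not in ("counts", "profile"):
        raise ValueError("mode must be 'counts' or 'profile'")
    if mode == "counts" and not np.allclose(v, np.round(v)):
        raise ValueError("counts mode requires integer abundances")

    nz = v[v > 0]
    S = float(nz.size)
    p = nz / N

    D = float(np.sum(p**2))
    H = float(-np.sum(p * np.log(p)))
    out = {
        "Taxa_S": S,
        "Individuals": N if mode == "counts" else np.nan,
        "Dominance_D": D,
        "Simpson_1-D": 1.0 - D,
        "Shannon_H": H,
        "Evenness": float(np.exp(H) / S),
        "Menhinick": S / np.sqrt(N),
        "Margalef": (S - 1.0) / np.log(N) if N > 1 else np.nan,
        "Equitability_J": H / np.log(S) if S > 1 else np.nan,
        "Berger-Parker": float(nz.max() / N),
    }
    if mode == "counts":
        n = np.round(nz).astype(np.int64)
        out["Brillouin"] = float((gammaln(N + 1) - np.sum(gammaln(n + 1))) / N)
        F1 = int(np.sum(n == 1))
        F2 = int(np.sum(n == 2))
        # bias-corrected form: defined even when no doubletons exist
        out["Chao1"] = S + F1 * (F1 - 1) / (2.0 * (F2 + 1))
        out["Fisher_alpha"] = fisher_alpha_solve(S, N) if S < N else np.nan
    else:
        out["Brillouin"] = np.nan
        out["Chao1"] = np.nan
        out["Fisher_alpha"] = np.nan
    return pd.Series(out).reindex(INDEX_NAMES)


def alpha_table(table: pd.DataFrame, mode: str = "counts", axis: int = 0) -> pd.DataFrame:
    """Alpha indices for every sample of a taxa x samples table (axis=0 columns)."""
    if axis == 1:
        table = table.T
    return pd.DataFrame({s: alpha_profile(table[s], mode=mode) for s in table.columns}).T
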