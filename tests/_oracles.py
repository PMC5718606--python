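"""Independent brute-force oracles used by the test suite.

These deliberately re-derive quantities by enumeration or naive formulas,
never by calling the implementation paths they check.
"""

from itertools import permutations

import numpy as np


def enumerate_group_pvalue(d2: np.ndarray, codes: np.ndarray, statistic) -> float:
    """Exact permutation p by full enumeration of distinct label assignments.

    ``statistic`` maps a label vector to a scalar; larger = more extreme.
    """
    obs = statistic(codes)
    seen = set()
    count = 0
    total = 0
    for perm in permutations(codes):
        if perm in seen:
            continue
        seen.add(perm)
        total += 1
        if statistic(np.asarray(perm)) >= obs - 1e-12:
            count += 1
    return count / total


def naive_pseudo_f(d2: np.ndarray, codes: np.ndarray) -> float:
    """PERMANOVA pseudo-F computed the slow way, pair by pair."""
    n = len(codes)
    k = len(set(codes))
    ss_total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            ss_total += d2[i, j]
    ss_total /= n
    ss_within = 0.0
    for g in set(codes):
        idx = [i for i in range(n) if codes[i] == g]
        s = 0.0
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                s += d2[idx[a], idx[b]]
        ss_within += s / len(idx)
    ss_among = ss_total - ss_within
    return (ss_among / (k - 1)) / (ss_within / (n - k))


def naive_bh(p: list[float]) -> np.ndarray:
    """Step-up BH by the textbook recipe."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    prev = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        prev = min(prev, p[idx] * m / rank)
        adj[idx] = prev
    return adj
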