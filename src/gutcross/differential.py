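"""Differential-taxon battery and its four-test congruency rule.

Four independent per-taxon votes identify "first responding" taxa between
cohorts, and a taxon counts as a hit only when all four agree:

1. a metastats-style test — unequal-variance t on relative abundances with a
   permutation null, routing sparse taxa (total count below a threshold)
   through Fisher's exact test on pooled counts; BH-FDR q across taxa;
2. indicator species analysis (IndVal = 100 * specificity * fidelity,
   permutation p);
3. a Kruskal-Wallis + effect-size gate standing in for LEfSe's
   "significant and large" semantics: the LDA score is replaced by the
   maximum pairwise log10 difference of group means (a one-dimensional
   surrogate; see docs/methods.md), significant when p < alpha AND
   effect >= threshold;
4. a core-microbiome ubiquity shift (the AWKS statistic from
   :mod:`gutcross.coremicro`).

Also provides the Firmicutes:Bacteroidetes ratio per sample and its rate of
change (least-squares slope of ln ratio vs day within participant x arm).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ._util import TestResult
from .beta import bh_fdr
from .coremicro import awks_test

DEFAULT_SPARSE_THRESHOLD = 8
DEFAULT_EFFECT_THRESHOLD = 0.15


def relative_abundance(table: pd.DataFrame) -> pd.DataFrame:
    """Column-normalized profiles; every column sums to 1."""
    sums = table.sum(axis=0)
    if (sums <= 0).any():
        raise ValueError("zero-total sample column(s)")
    return table.div(sums, axis=1)


def _welch_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Welch t statistics for two samples x-taxa blocks (taxa rows)."""
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va = a.var(axis=1, ddof=1) / a.shape[1]
    vb = b.var(axis=1, ddof=1) / b.shape[1]
    denom = np.sqrt(va + vb)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / denom
    return np.where(denom == 0, 0.0, t)


def metastats_test(
    profiles: pd.DataFrame,
    counts: pd.DataFrame,
    cohort_a: list,
    cohort_b: list,
    n_perm: int = 10_000,
    sparse_threshold: int = DEFAULT_SPARSE_THRESHOLD,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-taxon two-cohort differential abundance, metastats style.

    Abundant taxa: permutation two-sided p of the Welch t on relative
    abundances. Sparse taxa (pooled count < sparse_threshold): Fisher's exact
    on the pooled taxon-vs-rest 2x2 table. Returns a taxon-indexed frame with
    statistic/p/q plus the branch taken.
    """
    if len(cohort_a) < 3 or len(cohort_b) < 3:
        raise ValueError("both cohorts need >= 3 samples")
    rng = np.random.default_rng(seed)
    A = profiles[cohort_a].to_numpy(dtype=float)
    B = profiles[cohort_b].to_numpy(dtype=float)
    na = A.shape[1]
    pooled_counts = counts[cohort_a].sum(axis=1) + counts[cohort_b].sum(axis=1)
    sparse = pooled_counts.to_numpy() < sparse_threshold

    t_obs = _welch_t(A, B)
    X = np.concatenate([A, B], axis=1)
    exceed = np.zeros(X.shape[0])
    for _ in range(n_perm):
        order = rng.permutation(X.shape[1])
        Xp = X[:, order]
        exceed += np.abs(_welch_t(Xp[:, :na], Xp[:, na:])) >= np.abs(t_obs) - 1e-12
    p_perm = (1.0 + exceed) / (1.0 + n_perm)

    p = p_perm.copy()
    stat = t_obs.copy()
    total_a = counts[cohort_a].to_numpy().sum()
    total_b = counts[cohort_b].to_numpy().sum()
    for i in np.flatnonzero(sparse):
        ca = int(counts[cohort_a].iloc[i].sum())
        cb = int(counts[cohort_b].iloc[i].sum())
        stat[i], p[i] = stats.fisher_exact([[ca, total_a - ca], [cb, total_b - cb]])
    q = bh_fdr(p)
    return pd.DataFrame(
        {"statistic": stat, "p": p, "q": q, "branch": np.where(sparse, "fisher", "t")},
        index=profiles.index,
    )


def indval_test(
    profiles: pd.DataFrame, groups: pd.Series, n_perm: int = 1000, seed: int = 0
) -> pd.DataFrame:
    """Indicator value per taxon with a group-label permutation p.

    IndVal = 100 * max_g (A_ig * B_ig): A is the taxon's mean relative
    abundance in g over the sum of its group means (specificity), B its
    occupancy within g (fidelity).
    """
    groups = pd.Series(groups).reindex(profiles.columns)
    codes, uniques = pd.factorize(groups)
    if len(uniques) < 2:
        raise ValueError("need >= 2 groups")
    if (np.bincount(codes) == 0).any():
        raise ValueError("empty group")
    X = profiles.to_numpy(dtype=float)

    def indval(codes_: np.ndarray) -> np.ndarray:
        means = np.stack([X[:, codes_ == g].mean(axis=1) for g in range(len(uniques))], axis=1)
        occ = np.stack([(X[:, codes_ == g] > 0).mean(axis=1) for g in range(len(uniques))], axis=1)
        denom = means.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            spec = np.where(denom > 0, means / denom, 0.0)
        return 100.0 * np.max(spec * occ, axis=1)

    obs = indval(codes)
    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(obs)
    for _ in range(n_perm):
        exceed += indval(codes[rng.permutation(len(codes))]) >= obs - 1e-12
    p = (1.0 + exceed) / (1.0 + n_perm)
    return pd.DataFrame({"indval": obs, "p": p}, index=profiles.index)


def kw_effect_test(
    profiles: pd.DataFrame,
    groups: pd.Series,
    alpha: float = 0.05,
    effect_threshold: float = DEFAULT_EFFECT_THRESHOLD,
) -> pd.DataFrame:
    """Kruskal-Wallis across groups plus a log10 effect-size gate per taxon.

    Effect size is the maximum over group pairs of |log10(mean_1 + eps) -
    log10(mean_2 + eps)| with eps = half the table-wide minimum nonzero
    relative abundance (a pseudo-abundance below anything observed, so a
    k-fold mean difference scores ~log10(k)); a taxon is significant when
    p < alpha AND effect >= threshold. Constant taxa get p = 1 by convention.
    """
    groups = pd.Series(groups).reindex(profiles.columns)
    codes, uniques = pd.factorize(groups)
    if len(uniques) < 2:
        raise ValueError("need >= 2 groups")
    all_vals = profiles.to_numpy(dtype=float)
    nonzero_all = all_vals[all_vals > 0]
    eps = nonzero_all.min() / 2.0 if nonzero_all.size else 1e-12
    rows = []
    for taxon, row in profiles.iterrows():
        x = row.to_numpy(dtype=float)
        blocks = [x[codes == g] for g in range(len(uniques))]
        if np.ptp(x) == 0:
            h, p = 0.0, 1.0
        else:
            h, p = stats.kruskal(*blocks)
        means = np.array([b.mean() for b in blocks])
        lm = np.log10(means + eps)
        effect = float(np.max(lm) - np.min(lm))
        rows.append((taxon, float(h), float(p), effect, p < alpha and effect >= effect_threshold))
    return pd.DataFrame(
        rows, columns=["taxon", "H", "p", "effect", "significant"]
    ).set_index("taxon")


def congruency_report(
    metastats: pd.DataFrame,
    indval: pd.DataFrame,
    kw: pd.DataFrame,
    core_shift: pd.DataFrame,
    q_threshold: float = 0.05,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Conjunction of the four verdicts; congruent only when every test fires.

    All four inputs must cover the same taxon set. ``core_shift`` needs
    columns statistic/p (AWKS per taxon).
    """
    taxa = list(metastats.index)
    for other in (indval, kw, core_shift):
        if set(other.index) != set(taxa):
            raise ValueError("taxon sets differ between tests")
    report = pd.DataFrame(index=pd.Index(taxa, name="taxon"))
    report["metastats_q"] = metastats["q"]
    report["metastats_hit"] = metastats["q"] < q_threshold
    report["indval"] = indval["indval"]
    report["indval_hit"] = indval["p"] < p_threshold
    report["kw_effect"] = kw["effect"]
    report["kw_hit"] = kw["significant"]
    report["awks"] = core_shift["statistic"]
    report["awks_hit"] = core_shift["p"] < p_threshold
    report["congruent"] = (
        report["metastats_hit"] & report["indval_hit"] & report["kw_hit"] & report["awks_hit"]
    )
    return report


def run_battery(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    cohort_a: list,
    cohort_b: list,
    n_perm: int = 1000,
    metastats_perm: int = 10_000,
    seed: int = 0,
    sparse_threshold: int = DEFAULT_SPARSE_THRESHOLD,
    alpha: float = 0.05,
    effect_threshold: float = DEFAULT_EFFECT_THRESHOLD,
) -> pd.DataFrame:
    """Run all four tests on one two-cohort contrast and return the congruency report."""
    sub = counts[list(cohort_a) + list(cohort_b)]
    profiles = relative_abundance(sub)
    labels = pd.Series(
        ["A"] * len(cohort_a) + ["B"] * len(cohort_b), index=sub.columns
    )
    ms = metastats_test(
        profiles, sub, list(cohort_a), list(cohort_b),
        n_perm=metastats_perm, sparse_threshold=sparse_threshold, seed=seed,
    )
    iv = indval_test(profiles, labels, n_perm=n_perm, seed=seed + 1)
    kw = kw_effect_test(profiles, labels, alpha=alpha, effect_threshold=effect_threshold)
    core_rows = []
    for i, taxon in enumerate(profiles.index):
        res = awks_test(
            profiles, list(cohort_a), list(cohort_b), taxon, n_perm=n_perm, seed=seed + 2
        )
        core_rows.append((taxon, res.statistic, res.p_value))
    core = pd.DataFrame(core_rows, columns=["taxon", "statistic", "p"]).set_index("taxon")
    return congruency_report(ms, iv, kw, core)


def fb_ratio_series(
    counts: pd.DataFrame, taxonomy: pd.DataFrame, design: pd.DataFrame
) -> tuple[pd.Series, pd.DataFrame]:
    """Firmicutes:Bacteroidetes ratio per sample and its rate of change.

    Rate = least-squares slope of ln(ratio) versus day within each
    (participant, arm); samples with no Bacteroidetes reads get a missing
    ratio and are excluded from the fit.
    """
    phylum = taxonomy.loc[counts.index, "phylum"]
    firm = counts.loc[phylum == "Firmicutes"].sum(axis=0)
    bact = counts.loc[phylum == "Bacteroidetes"].sum(axis=0)
    ratio = firm / bact.replace(0, np.nan)
    ratio.name = "fb_ratio"
    rows = []
    meta = design.set_index("sample_id")
    for (pid, arm), grp in meta.groupby(["participant_id", "arm"]):
        r = np.log(ratio.reindex(grp.index).astype(float))
        ok = r.notna()
        if ok.sum() >= 2:
            slope = np.polyfit(grp.loc[ok, "day"].to_numpy(dtype=float), r[ok].to_numpy(), 1)[0]
        else:
            slope = np.nan
        rows.append((pid, arm, slope))
    rates = pd.DataFrame(rows, columns=["participant_id", "arm", "ln_ratio_slope_per_day"])
    return ratio, rates
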