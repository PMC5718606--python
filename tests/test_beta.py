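"""Distances, UniFrac, and the permutation-test battery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from skbio import DistanceMatrix
from skbio.stats.distance import mantel as skbio_mantel, permanova as skbio_permanova

from gutcross import beta

from _oracles import enumerate_group_pvalue, naive_bh, naive_pseudo_f


def table_from(cols: dict) -> pd.DataFrame:
    return pd.DataFrame(cols)


class TestRarefy:
    def test_column_at_depth_unchanged(self):
        t = table_from({"a": [3, 2, 5], "b": [10, 0, 0]})
        out = beta.rarefy_counts(t, 10)
        assert list(out["a"]) == [3, 2, 5]
        assert list(out["b"]) == [10, 0, 0]

    def test_conservation_and_determinism(self, small_counts):
        counts, _ = small_counts
        sub = counts.iloc[:, :6]
        depth = int(sub.sum(axis=0).min())
        r1 = beta.rarefy_counts(sub, depth, seed=3)
        r2 = beta.rarefy_counts(sub, depth, seed=3)
        assert (r1.sum(axis=0) == depth).all()
        pd.testing.assert_frame_equal(r1, r2)
        assert (r1 <= sub).all().all()

    def test_shallow_samples_dropped_with_warning(self):
        t = table_from({"deep": [50, 50], "shallow": [1, 1]})
        with pytest.warns(UserWarning):
            out = beta.rarefy_counts(t, 10)
        assert list(out.columns) == ["deep"]

    def test_depth_below_one_rejected(self):
        with pytest.raises(ValueError):
            beta.rarefy_counts(table_from({"a": [1]}), 0)


class TestDistances:
    def test_hand_values(self):
        t = table_from({"x": [2, 1, 0], "y": [1, 1, 1]})
        assert np.isclose(beta.pairwise_distance(t, "braycurtis")["x", "y"], 1 / 3)
        assert np.isclose(beta.pairwise_distance(t, "jaccard")["x", "y"], 1 / 3)
        # p=(2/3,1/3,0), q=(1/3,1/3,1/3): theta_yc sim = (1/3)/(2/9+1/3) = 3/5
        assert np.isclose(beta.pairwise_distance(t, "thetayc")["x", "y"], 2 / 5)
        # morisita-horn: 1 - 2*(1/3)/(5/9+1/3) = 1/4
        assert np.isclose(beta.pairwise_distance(t, "morisitahorn")["x", "y"], 1 / 4)

    @pytest.mark.parametrize("metric", beta.METRICS)
    def test_identical_samples_zero(self, metric):
        t = table_from({"x": [4, 2, 1], "y": [4, 2, 1]})
        assert beta.pairwise_distance(t, metric)["x", "y"] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("metric", beta.METRICS)
    def test_disjoint_samples_one(self, metric):
        t = table_from({"x": [5, 3, 0, 0], "y": [0, 0, 2, 7]})
        assert beta.pairwise_distance(t, metric)["x", "y"] == pytest.approx(1.0)

    @given(
        st.lists(
            st.lists(st.integers(min_value=0, max_value=50), min_size=4, max_size=4),
            min_size=3,
            max_size=6,
        ).filter(lambda rows: all(sum(r) > 0 for r in rows))
    )
    @settings(max_examples=40, deadline=None)
    def test_distance_axioms(self, rows):
        t = pd.DataFrame(np.asarray(rows).T, columns=[f"s{i}" for i in range(len(rows))])
        for metric in beta.METRICS:
            dm = beta.pairwise_distance(t, metric)
            d = dm.data
            assert np.allclose(d, d.T)
            assert np.allclose(np.diag(d), 0.0)
            assert (d >= -1e-12).all() and (d <= 1.0 + 1e-9).all()

    def test_zero_total_sample_rejected(self):
        t = table_from({"x": [1, 1], "y": [0, 0]})
        for metric in beta.METRICS:
            with pytest.raises(ValueError):
                beta.pairwise_distance(t, metric)


class TestUnifrac:
    # rooted star: zero-length internal edges contribute no branch length
    star = "((A:1,B:1):0.0,(C:1,D:1):0.0);"

    def test_identical_communities_zero(self):
        t = pd.DataFrame({"x": [3, 1, 0, 2], "y": [3, 1, 0, 2]}, index=list("ABCD"))
        for w in (False, True):
            assert beta.unifrac(t, self.star, weighted=w)["x", "y"] == pytest.approx(0.0)

    def test_star_tree_disjoint_unweighted_one(self):
        t = pd.DataFrame({"x": [3, 1, 0, 0], "y": [0, 0, 2, 2]}, index=list("ABCD"))
        assert beta.unifrac(t, self.star, weighted=False)["x", "y"] == pytest.approx(1.0)

    def test_two_leaf_tree_opposite_communities_weighted_one(self):
        t = pd.DataFrame({"x": [5, 0], "y": [0, 7]}, index=["A", "B"])
        dm = beta.unifrac(t, "(A:1,B:1);", weighted=True)
        assert dm["x", "y"] == pytest.approx(1.0)

    def test_weighted_star_tree_matches_l1_closed_form(self):
        # star tree, unit branches: weighted normalized UniFrac = L1/2 on proportions
        t = pd.DataFrame({"x": [6, 2, 2, 0], "y": [2, 2, 4, 2]}, index=list("ABCD"))
        p = t["x"] / t["x"].sum()
        q = t["y"] / t["y"].sum()
        expected = np.abs(p - q).sum() / (p + q).sum()
        assert beta.unifrac(t, self.star, weighted=True)["x", "y"] == pytest.approx(expected)

    def test_missing_taxon_rejected(self):
        t = pd.DataFrame({"x": [1, 1], "y": [1, 1]}, index=["A", "Z"])
        with pytest.raises(ValueError):
            beta.unifrac(t, "(A:1,B:1);")


class TestGroupTests:
    def toy_dm(self, rng, n=6):
        pts = rng.normal(size=(n, 3))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        return DistanceMatrix(d, [f"s{i}" for i in range(n)])

    def test_permanova_statistic_matches_naive_and_reference(self, rng):
        dm = self.toy_dm(rng, n=8)
        groups = ["a"] * 4 + ["b"] * 4
        res = beta.permanova(dm, groups, n_perm=99, seed=0)
        assert res.statistic == pytest.approx(naive_pseudo_f(dm.data**2, np.array([0] * 4 + [1] * 4)))
        ref = skbio_permanova(dm, grouping=groups, permutations=99)
        assert res.statistic == pytest.approx(ref["test statistic"])

    @pytest.mark.parametrize("method", [beta.permanova, beta.amova])
    def test_enumeration_oracle_small_instance(self, rng, method):
        dm = self.toy_dm(rng, n=6)
        groups = ["a", "a", "a", "b", "b", "b"]
        codes = np.array([0, 0, 0, 1, 1, 1])
        res = method(dm, groups, n_perm=2000, seed=1)

        def stat(c):
            return naive_pseudo_f(dm.data**2, c)

        exact = enumerate_group_pvalue(dm.data**2, codes, stat)
        mc_se = np.sqrt(exact * (1 - exact) / 2000)
        assert abs(res.p_value - exact) <= 2 * mc_se + 1e-3

    def test_separated_clusters_reach_minimal_p(self, rng):
        a = rng.normal(size=(10, 2)) * 0.01
        b = rng.normal(size=(10, 2)) * 0.01 + 100.0
        pts = np.vstack([a, b])
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        dm = DistanceMatrix(d, [f"s{i}" for i in range(20)])
        res = beta.permanova(dm, ["a"] * 10 + ["b"] * 10, n_perm=999, seed=2)
        assert res.p_value == pytest.approx(1 / 1000)

    def test_amova_invariant_to_within_group_relabelling(self, rng):
        dm = self.toy_dm(rng, n=8)
        g1 = ["a", "a", "a", "a", "b", "b", "b", "b"]
        r1 = beta.amova(dm, g1, n_perm=9, seed=0)
        # swapping which label names which group leaves the statistic unchanged
        g2 = ["b", "b", "b", "b", "a", "a", "a", "a"]
        r2 = beta.amova(dm, g2, n_perm=9, seed=0)
        assert r1.statistic == pytest.approx(r2.statistic)

    def test_homova_nonnegative_and_detects_inflated_dispersion(self, rng):
        hits = 0
        for s in range(20):
            local = np.random.default_rng(s)
            a = local.normal(size=(18, 3))
            b = local.normal(size=(18, 3)) * 4.0
            pts = np.vstack([a, b])
            d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
            dm = DistanceMatrix(d, [f"s{i}" for i in range(36)])
            res = beta.homova(dm, ["a"] * 18 + ["b"] * 18, n_perm=199, seed=s)
            assert res.statistic >= 0.0
            hits += res.p_value < 0.05
        assert hits >= 16  # >= 80% power at 4x dispersion, n = 18/group

    def test_group_size_validation(self, rng):
        dm = self.toy_dm(rng, n=4)
        with pytest.raises(ValueError):
            beta.permanova(dm, ["a", "a", "a", "b"], n_perm=9)
        with pytest.raises(ValueError):
            beta.permanova(dm, ["a"] * 4, n_perm=9)


class TestMantel:
    def test_self_correlation_is_one(self, rng):
        pts = rng.normal(size=(8, 2))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        dm = DistanceMatrix(d, [f"s{i}" for i in range(8)])
        res = beta.mantel(dm, dm, n_perm=99, seed=0)
        assert res.statistic == pytest.approx(1.0)
        assert res.extra["r_squared"] == pytest.approx(1.0)

    def test_positive_affine_transform_keeps_r_one(self, rng):
        pts = rng.normal(size=(8, 2))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        ids = [f"s{i}" for i in range(8)]
        d2 = 0.3 * d + 0.1
        np.fill_diagonal(d2, 0.0)
        res = beta.mantel(DistanceMatrix(d, ids), DistanceMatrix(d2, ids), n_perm=99, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_statistic_matches_reference_library(self, rng):
        pts1, pts2 = rng.normal(size=(7, 2)), rng.normal(size=(7, 2))
        ids = [f"s{i}" for i in range(7)]
        dms = []
        for pts in (pts1, pts2):
            d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
            dms.append(DistanceMatrix(d, ids))
        res = beta.mantel(dms[0], dms[1], n_perm=99, seed=0)
        r_ref, _, _ = skbio_mantel(dms[0], dms[1], permutations=0)
        assert res.statistic == pytest.approx(r_ref)

    def test_label_mismatch_rejected(self, rng):
        d = np.zeros((3, 3))
        with pytest.raises(ValueError):
            beta.mantel(DistanceMatrix(d, ["a", "b", "c"]), DistanceMatrix(d, ["a", "c", "b"]))


class TestBH:
    def test_hand_example(self):
        assert np.allclose(beta.bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert beta.bh_fdr([0.2])[0] == pytest.approx(0.2)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_matches_textbook_stepup_and_dominates_raw(self, ps):
        adj = beta.bh_fdr(ps)
        assert np.allclose(adj, naive_bh(ps))
        assert (adj >= np.asarray(ps) - 1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            beta.bh_fdr([0.5, 1.5])
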