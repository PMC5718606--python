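"""Generator contracts: design layout, planted effects, reproducibility."""

import numpy as np
import pandas as pd
import pytest

from gutcross import synthetic as syn


class TestDesign:
    def test_default_layout_is_9x3x6(self, small_design):
        assert len(small_design) == 9 * 3 * 6
        assert small_design["sample_id"].is_unique
        triples = small_design[["participant_id", "arm", "day"]]
        assert not triples.duplicated().any()

    def test_two_participants_cover_all_arms(self):
        cfg = syn.GeneratorConfig(n_participants=2, seed=3)
        d = syn.generate_design(cfg)
        assert len(d) == 2 * 3 * 6
        for _, grp in d.groupby("participant_id"):
            assert set(grp["arm"]) == set(syn.ARMS)

    def test_week_mapping(self, small_design):
        expected = {-5: 0, -1: 0, 3: 1, 10: 2, 18: 3, 21: 4}
        assert all(expected[d] == w for d, w in zip(small_design["day"], small_design["week"]))

    def test_same_seed_reproduces_rows(self, small_config, small_design):
        again = syn.generate_design(small_config)
        pd.testing.assert_frame_equal(again, small_design)

    def test_rejects_single_participant(self):
        with pytest.raises(ValueError):
            syn.GeneratorConfig(n_participants=1)

    def test_dropout_removes_rows(self):
        cfg = syn.GeneratorConfig(seed=5, dropout_rate=0.3)
        d = syn.generate_design(cfg)
        assert 0 < len(d) < 162


class TestCounts:
    def test_columns_match_design_and_are_positive(self, small_design, small_counts):
        counts, _ = small_counts
        assert list(counts.columns) == list(small_design["sample_id"])
        assert (counts.sum(axis=0) > 0).all()
        assert (counts.to_numpy() >= 0).all()

    def test_ledger_names_exactly_the_planted_cells(self, small_design, small_counts):
        counts, ledger = small_counts
        assert ledger["effect_taxa"] == ["Bacteroides"]
        meta = small_design.set_index("sample_id")
        expected = meta[(meta["arm"] == "HBR") & meta["day"].isin([18, 21])].index
        assert sorted(ledger["effect_samples"]) == sorted(expected)

    def test_null_mode_has_empty_effect_ledger(self, null_counts):
        _, ledger = null_counts
        assert ledger["effect_taxa"] == []
        assert ledger["effect_samples"] == []

    def test_null_mode_equal_bacteroides_across_arms(self):
        """fold = 1: group mean Bacteroides relabund equal across arms (MC error)."""
        ratios = []
        for s in range(30):
            cfg = syn.GeneratorConfig(seed=500 + s, scale=0.02, bacteroides_fold=1.0)
            d = syn.generate_design(cfg)
            counts, _ = syn.generate_counts(d, cfg)
            rel = counts / counts.sum(axis=0)
            meta = d.set_index("sample_id")
            hbr = rel.loc["Bacteroides", meta[(meta.arm == "HBR") & (meta.day == 21)].index].mean()
            hamb = rel.loc["Bacteroides", meta[(meta.arm == "HAmb") & (meta.day == 21)].index].mean()
            ratios.append(hbr / hamb)
        assert abs(np.mean(ratios) - 1.0) < 0.1

    def test_fold_two_doubles_mean_relabund(self):
        """Planted fold 2: HBR/HAmb day-21 Bacteroides relabund ratio ~ 2 (MC mean)."""
        num, den = [], []
        for s in range(120):
            cfg = syn.GeneratorConfig(seed=900 + s, scale=0.02)
            d = syn.generate_design(cfg)
            counts, _ = syn.generate_counts(d, cfg)
            rel = counts / counts.sum(axis=0)
            meta = d.set_index("sample_id")
            num.append(rel.loc["Bacteroides", meta[(meta.arm == "HBR") & (meta.day == 21)].index].mean())
            den.append(rel.loc["Bacteroides", meta[(meta.arm == "HAmb") & (meta.day == 21)].index].mean())
        ratio = np.mean(num) / np.mean(den)
        assert 1.8 < ratio < 2.2

    def test_rejects_nonpositive_fold(self):
        with pytest.raises(ValueError):
            syn.GeneratorConfig(bacteroides_fold=0.0)

    def test_same_seed_bitwise_identical(self, small_design, small_config, small_counts):
        counts, _ = small_counts
        again, _ = syn.generate_counts(small_design, small_config)
        pd.testing.assert_frame_equal(again, counts)

    def test_baseline_is_firmicutes_bacteroidetes_dominated(self):
        base = syn.baseline_composition()
        tax = syn.taxonomy_table()
        share = base.groupby(tax.loc[base.index, "phylum"].to_numpy()).sum()
        assert share["Firmicutes"] + share["Bacteroidetes"] >= 0.80


class TestTree:
    def test_two_taxa(self):
        nwk = syn.generate_tree(["A", "B"], seed=1)
        assert nwk.count("(") == 1 and "A" in nwk and "B" in nwk

    def test_leaf_set_matches_taxa(self, small_counts):
        from skbio import TreeNode

        counts, _ = small_counts
        nwk = syn.generate_tree(list(counts.index), seed=2)
        tree = TreeNode.read([nwk])
        assert {t.name for t in tree.tips()} == set(counts.index)
        assert all(t.length > 0 for t in tree.traverse() if t.length is not None)

    def test_same_seed_byte_identical(self):
        taxa = [f"t{i}" for i in range(10)]
        assert syn.generate_tree(taxa, seed=9) == syn.generate_tree(taxa, seed=9)

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError):
            syn.generate_tree(["A", "A"], seed=0)


class TestSpectra:
    def test_grid_has_121_points_per_dilution(self, small_design, small_config):
        spectra, _, _ = syn.generate_spectra(small_design.head(2), small_config)
        per = spectra.groupby(["sample", "dilution"]).size()
        assert (per == 121).all()
        assert set(spectra["dilution"]) == {10, 50, 100}

    def test_flat_noiseless_spectrum_is_constant(self, small_design):
        cfg = syn.GeneratorConfig(seed=4, spec_a0=1.0, spec_slope=0.0,
                                  spec_bands=False, spec_noise_sd=0.0)
        spectra, _, _ = syn.generate_spectra(small_design.head(1), cfg)
        one = spectra[spectra["dilution"] == 10]["absorbance"]
        assert np.allclose(one, one.iloc[0])

    def test_dilution_linearity_without_noise(self, small_design):
        cfg = syn.GeneratorConfig(seed=4, spec_noise_sd=0.0)
        spectra, _, _ = syn.generate_spectra(small_design.head(1), cfg)
        wide = spectra.pivot_table(index="wavelength_nm", columns="dilution", values="absorbance")
        assert np.allclose(wide[100], wide[10] / 10.0)
        assert np.allclose(wide[50], wide[10] / 5.0)


class TestPeaksMetadataConductivity:
    def test_shared_registry_and_totals(self, small_design, small_config):
        peaks = syn.generate_peak_tables(small_design, small_config)
        for cls, table in peaks.items():
            assert 10 <= table.shape[1] <= 30
            assert (table.to_numpy() > 0).all()
            assert np.allclose(table.sum(axis=1), table.to_numpy().sum(axis=1))

    def test_planted_peak_effect_shifts_one_peak(self, small_design):
        cfg = syn.GeneratorConfig(seed=6, peak_effect_class="sterol", peak_effect_factor=5.0)
        base = syn.GeneratorConfig(seed=6)
        with_eff = syn.generate_peak_tables(small_design, cfg)["sterol"]
        without = syn.generate_peak_tables(small_design, base)["sterol"]
        meta = small_design.set_index("sample_id")
        hit = meta[(meta.arm == "HBR") & meta.day.isin([18, 21])].index
        ratio = with_eff.loc[hit].iloc[:, 0] / without.loc[hit].iloc[:, 0]
        assert np.allclose(ratio, 5.0)
        others = with_eff.drop(index=hit)
        pd.testing.assert_frame_equal(others, without.drop(index=hit))

    def test_metadata_widths_and_determinism(self, small_design, small_config, small_counts):
        _, ledger = small_counts
        mats, coupling = syn.generate_metadata_matrices(
            small_design, small_config, gradient=ledger["gradient"]
        )
        assert [m.shape[1] for m in mats.values()] == [109, 12, 110]
        again, _ = syn.generate_metadata_matrices(
            small_design, small_config, gradient=ledger["gradient"]
        )
        for name in mats:
            pd.testing.assert_frame_equal(mats[name], again[name])
        for name, cols in coupling["coupled"].items():
            assert all(c in mats[name].columns for c in cols)

    def test_uncoupled_metadata_independent_of_gradient(self, small_design, small_config, small_counts):
        _, ledger = small_counts
        mats, _ = syn.generate_metadata_matrices(small_design, small_config, gradient=None)
        g = ledger["gradient"]["axis1"].reindex(small_design["sample_id"]).to_numpy()
        r = np.array([
            np.corrcoef(mats["chem"].iloc[:, j], g)[0, 1] for j in range(20)
        ])
        assert np.abs(r).max() < 0.35  # 162 samples: null |r| stays small

    def test_conductivity_week1_increase_matches_config(self, small_design, small_config):
        _, _, truth = syn.generate_conductivity(small_design, small_config)
        iec = truth["true_iec"]
        meta = small_design.set_index("sample_id")
        for arm, expected in (("HBR", 1.67), ("NBR", 1.32), ("HAmb", 1.0)):
            pre = iec[meta[(meta.arm == arm) & (meta.day < 0)].index].mean()
            post = iec[meta[(meta.arm == arm) & (meta.day >= 3)].index].mean()
            assert abs(post / pre - expected) < 0.08
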