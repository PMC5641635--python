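import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from codonquant import (SampleDesign, codon_enrichment, compare_codon_totals,
                        fold_changes, heatmap_layout, regress_fc_on_aaa,
                        weighted_codon_totals)
from codonquant.errors import DegenerateDesignError, ValidationError
from codonquant.genetics import SENSE_CODONS
from codonquant.stats import compare_all_codons, loglog_table

DESIGN = SampleDesign.default(5, 5)
SAMPLES = list(DESIGN.sample_ids)


def quant_frame(values: dict[str, list[float]]) -> pd.DataFrame:
    df = pd.DataFrame(values, index=SAMPLES).T
    df.index.name = "peptide"
    return df


class TestWeightedCodonTotals:
    def test_single_peptide(self, make_profiles):
        profiles = make_profiles({"KK": ["AAA", "AAA"]})
        quant = quant_frame({"KK": [10.0] + [0.0] * 9})
        totals = weighted_codon_totals(quant, profiles)
        assert totals.loc["Ctrl1", "AAA"] == 20.0

    def test_two_peptides_accumulate(self, make_profiles):
        profiles = make_profiles({"K": ["AAA"], "KKK": ["AAA"] * 3})
        quant = quant_frame({"K": [5.0] + [0.0] * 9,
                             "KKK": [2.0] + [0.0] * 9})
        totals = weighted_codon_totals(quant, profiles)
        assert totals.loc["Ctrl1", "AAA"] == 11.0

    def test_zero_abundance_annihilates(self, make_profiles):
        profiles = make_profiles({"KK": ["AAA", "AAG"]})
        quant = quant_frame({"KK": [0.0] * 10})
        assert (weighted_codon_totals(quant, profiles).to_numpy() == 0).all()

    def test_peptide_without_profile_is_hard_error(self, make_profiles):
        profiles = make_profiles({"KK": ["AAA", "AAA"]})
        quant = quant_frame({"KK": [1.0] * 10, "MISSING": [1.0] * 10})
        with pytest.raises(ValidationError, match="MISSING"):
            weighted_codon_totals(quant, profiles)

    def test_scaling_linearity(self, small_result):
        quant = small_result["peptide_quant"]
        profiles = small_result["profiles"]
        base = weighted_codon_totals(quant, profiles)
        scaled = weighted_codon_totals(quant * 2.5, profiles)
        np.testing.assert_allclose(scaled.to_numpy(), 2.5 * base.to_numpy())


def totals_frame(ctrl, ko, codon="AAA"):
    design = SampleDesign.default(len(ctrl), len(ko))
    df = pd.DataFrame({codon: list(ctrl) + list(ko)},
                      index=list(design.sample_ids))
    return df, design


class TestCompareCodonTotals:
    def test_identical_groups_give_t0_p1(self):
        totals, design = totals_frame([10, 10, 10], [10, 10, 10])
        row = compare_codon_totals(totals, design, "AAA")
        assert row.t_statistic == 0.0 and row.p_value == 1.0

    def test_pooled_t_matches_closed_form(self):
        # closed-form pooled-variance t with 4 df, computed independently:
        # means 2 and 5, pooled sd 1, se = sqrt(2/3)
        totals, design = totals_frame([1, 2, 3], [4, 5, 6])
        row = compare_codon_totals(totals, design, "AAA")
        t_expected = (2.0 - 5.0) / np.sqrt(2.0 / 3.0)
        p_expected = 2.0 * sps.t.sf(abs(t_expected), df=4)
        assert row.t_statistic == pytest.approx(t_expected)
        assert row.t_statistic < 0
        assert row.p_value == pytest.approx(p_expected)

    def test_single_sample_groups_rejected(self):
        totals, design = totals_frame([1, 2], [3])
        with pytest.raises(DegenerateDesignError):
            compare_codon_totals(totals, design, "AAA")

    def test_relabeling_within_group_leaves_statistics_unchanged(
            self, small_result):
        totals = small_result["weighted_totals"]
        design = small_result["design"]
        base = compare_all_codons(totals, design)
        ctrl = list(design.samples_in("control"))
        shuffled = totals.rename(index=dict(zip(ctrl, ctrl[::-1])))
        permuted = compare_all_codons(shuffled, design)
        pd.testing.assert_frame_equal(base, permuted)


class TestFoldChanges:
    def test_four_fold_down(self):
        quant = quant_frame({"p": [100.0] * 5 + [25.0] * 5})
        fc = fold_changes(quant, DESIGN, pseudocount=0.0)
        assert fc.loc["p", "log2fc"] == pytest.approx(-2.0)
        assert bool(fc.loc["p", "is_down_2x"])

    def test_just_under_two_fold_not_flagged(self):
        quant = quant_frame({"p": [100.0] * 5 + [51.0] * 5})
        fc = fold_changes(quant, DESIGN, pseudocount=0.0)
        assert fc.loc["p", "log2fc"] == pytest.approx(np.log2(0.51))
        assert not bool(fc.loc["p", "is_down_2x"])

    def test_equal_means_give_zero(self):
        quant = quant_frame({"p": [42.0] * 10})
        fc = fold_changes(quant, DESIGN)
        assert fc.loc["p", "log2fc"] == 0.0
        assert not bool(fc.loc["p", "is_down_2x"])

    def test_all_zero_unit_dropped_and_counted(self):
        quant = quant_frame({"p": [1.0] * 10, "z": [0.0] * 10})
        fc = fold_changes(quant, DESIGN)
        assert "z" not in fc.index
        assert fc.attrs["n_dropped_absent"] == 1

    def test_pseudocount_keeps_ratios_finite(self):
        quant = quant_frame({"p": [100.0] * 5 + [0.0] * 5})
        fc = fold_changes(quant, DESIGN, pseudocount=0.5)
        assert np.isfinite(fc.loc["p", "log2fc"])


class TestCodonEnrichment:
    def test_pure_aaa_down_set_ranks_first(self, make_profiles):
        profiles = make_profiles({"KK": ["AAA", "AAA"],
                                  "MA": ["ATG", "GCT"]})
        enr = codon_enrichment(profiles, ["KK"]).set_index("codon")
        assert enr.loc["AAA", "freq_down_percent"] == pytest.approx(100.0)
        assert enr.loc["AAA", "rank"] == 1

    def test_down_equals_total_gives_zero_deltas(self, make_profiles):
        profiles = make_profiles({"KK": ["AAA", "AAA"],
                                  "MA": ["ATG", "GCT"]})
        enr = codon_enrichment(profiles, ["KK", "MA"])
        np.testing.assert_allclose(enr["delta_percent"], 0.0)
        # alphabetical tie-break makes ranks 1..61 in codon order
        assert list(enr["rank"]) == list(range(1, 62))

    def test_hand_computed_deltas(self, make_profiles):
        # total codons: AAA,GCT,GCT,GCT -> AAA 25%, GCT 75%
        # down = {"GG"}: GCT 100% -> delta GCT +25, AAA -25
        profiles = make_profiles({"KA": ["AAA", "GCT"],
                                  "GG": ["GCT", "GCT"]})
        enr = codon_enrichment(profiles, ["GG"]).set_index("codon")
        assert enr.loc["GCT", "delta_percent"] == pytest.approx(25.0)
        assert enr.loc["AAA", "delta_percent"] == pytest.approx(-25.0)
        assert enr.loc["GCT", "rank"] == 1

    def test_empty_down_set_is_undefined_flagged(self, make_profiles):
        profiles = make_profiles({"KA": ["AAA", "GCT"]})
        enr = codon_enrichment(profiles, [])
        assert enr.attrs["undefined"]
        assert enr["delta_percent"].isna().all()

    def test_down_outside_total_rejected(self, make_profiles):
        profiles = make_profiles({"KA": ["AAA", "GCT"],
                                  "GG": ["GCT", "GCT"]})
        with pytest.raises(ValidationError):
            codon_enrichment(profiles, ["GG"], total_set=["KA"])

    def test_frequency_columns_sum_to_100(self, small_result):
        enr = small_result["enrichment"]
        assert enr["freq_total_percent"].sum() == pytest.approx(100, abs=1e-9)
        assert enr["freq_down_percent"].sum() == pytest.approx(100, abs=1e-9)
        assert sorted(enr["rank"]) == list(range(1, 62))


class TestHeatmapLayout:
    def test_zero_deltas_give_zero_matrix_with_3_stops(self, make_profiles):
        profiles = make_profiles({"KA": ["AAA", "GCT"]})
        enr = codon_enrichment(profiles, ["KA"])
        mat = heatmap_layout(enr)
        assert mat.shape == (16, 4)
        assert int(mat.isna().sum().sum()) == 3
        np.testing.assert_allclose(mat.fillna(0.0).to_numpy(), 0.0)

    def test_single_nonzero_cell_lands_on_aaa_position(self):
        enr = pd.DataFrame({"codon": list(SENSE_CODONS),
                            "delta_percent": 0.0})
        enr.loc[enr["codon"] == "AAA", "delta_percent"] = 7.0
        mat = heatmap_layout(enr)
        assert mat.loc[("A", "A"), "A"] == 7.0
        assert np.nansum(mat.to_numpy()) == 7.0

    def test_61_of_64_cells_populated(self, small_result):
        mat = heatmap_layout(small_result["enrichment"])
        assert mat.size == 64
        assert int(mat.notna().sum().sum()) == 61
        for stop_pos in [(("T", "A"), "A"), (("T", "A"), "G"),
                         (("T", "G"), "A")]:
            assert np.isnan(mat.loc[stop_pos[0], stop_pos[1]])


class TestRegression:
    def _data(self, rng, slope, n_prot=30, peps_per_prot=8, noise=0.3):
        rows, fc = [], {}
        for i in range(n_prot):
            pct = float(rng.uniform(0, 8))
            base_fc = slope * pct + rng.normal(0, noise)
            for j in range(peps_per_prot):
                pep = f"P{i}_{j}"
                length = 20
                n_aaa = int(round(pct / 100 * length))
                rows.append({"peptide": pep, "protein_id": f"PR{i}",
                             "start_aa": 0, "length": length,
                             **{c: 0 for c in SENSE_CODONS},
                             "AAA": n_aaa})
                fc[pep] = base_fc + rng.normal(0, noise / 2)
        profiles = pd.DataFrame(rows)
        fc_table = pd.DataFrame({"log2fc": pd.Series(fc)})
        return profiles, fc_table

    def test_recovers_negative_slope(self):
        rng = np.random.default_rng(0)
        profiles, fc_table = self._data(rng, slope=-0.3)
        res = regress_fc_on_aaa(fc_table, profiles)
        assert res.slope < 0
        assert res.p_value < 0.01
        assert res.standard_error > 0 or not res.converged

    def test_null_slope_covered_by_2se(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            profiles, fc_table = self._data(rng, slope=0.0)
            res = regress_fc_on_aaa(fc_table, profiles)
            if abs(res.slope) <= 2 * res.standard_error:
                hits += 1
        assert hits >= 16  # ~95% nominal coverage

    def test_constant_fold_change_degenerate(self):
        rng = np.random.default_rng(1)
        profiles, fc_table = self._data(rng, slope=0.0)
        fc_table["log2fc"] = 0.0
        res = regress_fc_on_aaa(fc_table, profiles)
        assert res.slope == 0.0 and res.p_value == 1.0
        assert not res.converged

    def test_constant_percent_aaa_rejected(self):
        rng = np.random.default_rng(2)
        profiles, fc_table = self._data(rng, slope=0.0)
        profiles["AAA"] = 2
        with pytest.raises(DegenerateDesignError):
            regress_fc_on_aaa(fc_table, profiles)

    def test_too_few_peptides_rejected(self):
        rng = np.random.default_rng(3)
        profiles, fc_table = self._data(rng, slope=0.0, n_prot=2,
                                        peps_per_prot=2)
        with pytest.raises(DegenerateDesignError):
            regress_fc_on_aaa(fc_table, profiles)


class TestLogLog:
    def test_flags_two_fold_changes_in_both_directions(self):
        fc = pd.DataFrame({
            "mean_control": [100.0, 100.0, 100.0],
            "mean_ko": [400.0, 100.0, 25.0],
            "log2fc": [2.0, 0.0, -2.0]},
            index=["up", "flat", "down"])
        out = loglog_table(fc)
        assert list(out["is_changed_2x"]) == [True, False, True]
        assert out.loc["up", "log10_mean_ko"] == pytest.approx(np.log10(400))
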