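"""Differential expression: transform, Student t, DEP filters, volcano."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from synprot.dep import (
    ComparisonSpec,
    compare_groups,
    filter_deps,
    filter_sd_down,
    log2_transform_and_normalize,
    volcano_table,
)
from synprot.io import ProteinQuantTable
from synprot.simulate import SynthConfig, synth_tmt


def make_table(num_rows, den_rows):
    """3v3 table from explicit log2 values (CTL = denominator)."""
    num = np.atleast_2d(np.asarray(num_rows, dtype=float))
    den = np.atleast_2d(np.asarray(den_rows, dtype=float))
    samples = ["b1_PS_1", "b1_PS_2", "b1_PS_3", "b1_CTL_1", "b1_CTL_2", "b1_CTL_3"]
    ids = [f"P{i}" for i in range(num.shape[0])]
    intensities = pd.DataFrame(np.hstack([num, den]),
                               index=pd.Index(ids, name="protein_id"), columns=samples)
    design = pd.DataFrame({"condition": ["PS"] * 3 + ["CTL"] * 3, "batch": [1] * 6},
                          index=pd.Index(samples, name="sample"))
    return ProteinQuantTable(intensities=intensities,
                             gene_symbols=pd.Series(ids, index=intensities.index),
                             log2_transformed=True).with_design(design)


SPEC = ComparisonSpec("PS/C", "PS", "CTL", 1)


class TestTransform:
    def test_constant_sample_centered_to_zero(self, small_quant_table):
        t = small_quant_table
        const = t.intensities.copy()
        const.loc[:, :] = 64.0
        table = ProteinQuantTable(intensities=const, gene_symbols=t.gene_symbols,
                                  condition=t.condition, batch=t.batch)
        out = log2_transform_and_normalize(table, "median_center")
        assert np.all(out.intensities.to_numpy() == 0.0)
        out2 = log2_transform_and_normalize(table, "none")
        assert np.all(out2.intensities.to_numpy() == 6.0)

    def test_post_centering_sample_medians_are_zero(self, small_quant_table):
        out = log2_transform_and_normalize(small_quant_table, "median_center")
        np.testing.assert_allclose(out.intensities.median(axis=0), 0.0, atol=1e-12)

    def test_all_missing_sample_rejected(self, small_quant_table):
        t = small_quant_table
        broken = t.intensities.copy()
        broken.iloc[:, 0] = np.nan
        table = ProteinQuantTable(intensities=broken, gene_symbols=t.gene_symbols,
                                  condition=t.condition, batch=t.batch)
        with pytest.raises(ValueError, match="all-missing"):
            log2_transform_and_normalize(table)


class TestCompareGroups:
    def test_identical_groups_give_t0_p1(self):
        table = make_table([[5, 6, 7]], [[5, 6, 7]])
        res = compare_groups(table, SPEC).table.iloc[0]
        assert res["log2_fc"] == 0.0 and res["t_stat"] == 0.0 and res["p_value"] == 1.0

    def test_zero_variance_doubling_flagged_with_lfc_1(self):
        # numerator = 2x denominator on linear scale, no within-group spread
        table = make_table([[6, 6, 6]], [[5, 5, 5]])
        res = compare_groups(table, SPEC).table.iloc[0]
        assert res["log2_fc"] == 1.0
        assert res["flag"] == "zero_variance"
        assert np.isnan(res["p_value"]) and not res["is_dep"]

    def test_matches_closed_form_pooled_t_and_scipy(self):
        """3v3 fixture: t and p agree with the textbook pooled-SD formula
        (df = 4) and with an independent scipy recomputation to 1e-10."""
        num, den = [4.1, 5.3, 4.8], [3.2, 3.9, 3.0]
        res = compare_groups(make_table([num], [den]), SPEC).table.iloc[0]
        m1, m2 = np.mean(num), np.mean(den)
        sp = np.sqrt((np.var(num, ddof=1) * 2 + np.var(den, ddof=1) * 2) / 4)
        t_ref = (m1 - m2) / (sp * np.sqrt(1 / 3 + 1 / 3))
        p_ref = 2 * stats.t.sf(abs(t_ref), 4)
        assert res["t_stat"] == pytest.approx(t_ref, abs=1e-10)
        assert res["p_value"] == pytest.approx(p_ref, abs=1e-10)
        t_sp, p_sp = stats.ttest_ind(num, den, equal_var=True)
        assert res["t_stat"] == pytest.approx(t_sp, abs=1e-10)
        assert res["p_value"] == pytest.approx(p_sp, abs=1e-10)

    def test_swapping_groups_negates_lfc_and_preserves_p(self, default_tmt):
        table, _ = default_tmt
        norm = log2_transform_and_normalize(table)
        fwd = compare_groups(norm, ComparisonSpec("PS/C", "PS", "CTL", 1)).table
        rev = compare_groups(norm, ComparisonSpec("C/PS", "CTL", "PS", 1)).table
        np.testing.assert_array_equal(fwd["log2_fc"], -rev["log2_fc"])
        np.testing.assert_array_equal(fwd["p_value"], rev["p_value"])

    def test_insufficient_replicates_flagged_not_dropped(self):
        table = make_table([[5, np.nan, np.nan]], [[3, 4, 5]])
        res = compare_groups(table, SPEC).table
        assert len(res) == 1
        assert res.iloc[0]["flag"] == "insufficient_replicates"
        assert not res.iloc[0]["is_dep"]

    def test_empty_group_after_batch_scoping_errors(self, small_quant_table):
        norm = log2_transform_and_normalize(small_quant_table)
        with pytest.raises(ValueError, match="PS/C.b2"):
            compare_groups(norm, ComparisonSpec("PS/C.b2", "PS", "CTL", 2))

    def test_welch_option_runs(self):
        res = compare_groups(make_table([[4, 5, 6]], [[1, 3, 5]]), SPEC, test="welch")
        assert np.isfinite(res.table.iloc[0]["p_value"])

    def test_determinism_bit_identical(self, default_tmt):
        table, _ = default_tmt
        norm = log2_transform_and_normalize(table)
        a = compare_groups(norm, SPEC).table
        b = compare_groups(norm, SPEC).table
        pd.testing.assert_frame_equal(a, b)


class TestDepFilters:
    def test_threshold_edges(self):
        # p = 0.04 with |lfc| = 0.60 is a DEP; |lfc| = 0.50 is not
        rows = pd.DataFrame({
            "gene_symbol": ["A", "B"], "log2_fc": [0.60, 0.50],
            "t_stat": [3.0, 3.0], "p_value": [0.04, 0.04],
            "q_value": [0.1, 0.1], "n_num": [3, 3], "n_den": [3, 3],
            "is_dep": [True, False], "direction": ["up", "up"], "flag": ["", ""],
        }, index=["P1", "P2"])
        from synprot.dep import ComparisonResult
        res = ComparisonResult(SPEC, rows, 0.05, 0.58)
        up, down = filter_deps(res)
        assert list(up.index) == ["P1"] and len(down) == 0

    def test_dep_set_equals_brute_force_scan(self, default_tmt):
        """On a 2000-protein synthetic contrast the DEP set equals an
        independent per-row scan of p < 0.05 and |log2FC| > 0.58."""
        table, _ = default_tmt
        norm = log2_transform_and_normalize(table)
        res = compare_groups(norm, SPEC)
        expected = set()
        for pid, row in res.table.iterrows():
            if (row["flag"] == "" and row["p_value"] < 0.05
                    and abs(row["log2_fc"]) > 0.58):
                expected.add(pid)
        assert set(res.table.index[res.table["is_dep"]]) == expected
        up, down = filter_deps(res)
        assert len(up) + len(down) == len(expected)

    def test_sd_down_rule_matches_brute_force_z(self, default_tmt):
        table, _ = default_tmt
        norm = log2_transform_and_normalize(table)
        res = compare_groups(norm, SPEC)
        got = filter_sd_down(res, sd_multiplier=1.96)
        fc = res.table["log2_fc"]
        z = (fc - fc.mean()) / fc.std(ddof=1)
        expected = res.table[(res.table["p_value"] < 0.05) & (z < -1.96)
                             & (res.table["flag"] == "")]
        assert list(got.index) == list(expected.index)
        assert (got["log2_fc"] < 0).all()

    def test_sd_down_zero_sd_errors(self):
        table = make_table([[5, 6, 7], [5, 6, 7]], [[5, 6, 7], [5, 6, 7]])
        res = compare_groups(table, SPEC)
        with pytest.raises(ValueError, match="zero standard deviation"):
            filter_sd_down(res)


class TestVolcano:
    def test_y_axis_is_neg_log10_p(self):
        table = make_table([[4.1, 5.3, 4.8]], [[3.2, 3.9, 3.0]])
        res = compare_groups(table, SPEC)
        res.table.loc["P0", "p_value"] = 0.01
        v = volcano_table(res)
        assert v.loc["P0", "neg_log10_p"] == pytest.approx(2.0)
        res.table.loc["P0", "p_value"] = 1.0
        assert volcano_table(res).loc["P0", "neg_log10_p"] == 0.0

    def test_p_zero_floored_and_flagged(self):
        table = make_table([[4.1, 5.3, 4.8]], [[3.2, 3.9, 3.0]])
        res = compare_groups(table, SPEC)
        res.table.loc["P0", "p_value"] = 0.0
        v = volcano_table(res)
        assert np.isfinite(v.loc["P0", "neg_log10_p"])
        assert "p_floored" in v.loc["P0", "flag"]

    def test_volcano_dep_flag_consistent_with_filter(self, default_tmt):
        table, _ = default_tmt
        norm = log2_transform_and_normalize(table)
        res = compare_groups(norm, SPEC)
        v = volcano_table(res)
        up, down = filter_deps(res)
        assert set(v.index[v["is_dep"]]) == set(up.index) | set(down.index)
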