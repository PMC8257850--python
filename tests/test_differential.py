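import numpy as np
import pandas as pd
import pytest

from merip_conjoint.differential import (
    test_diff_genes as diff_genes,
    test_diff_peaks as diff_peaks,
)
from merip_conjoint import (
    CountTable,
    QpcrRecord,
    bh_adjust,
    ddct_relative_expression,
    log2_intensity_cdf,
    normalize_library_sizes,
    pooled_fisher_test,
    volcano_labels,
)

from oracles import fisher_two_sided


class TestBH:
    def test_single_pvalue_is_identity(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_hand_computed_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_all_ones(self):
        assert bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0] * 3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    def test_adjusted_at_least_raw_and_permutation_invariant(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=40)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-12).all()
        perm = rng.permutation(40)
        assert bh_adjust(p[perm]) == pytest.approx(adj[perm])


class TestPooledFisher:
    def test_symmetric_table(self):
        p, lfc = pooled_fisher_test(10, 10, 10, 10)
        assert p == pytest.approx(1.0)
        assert lfc == 0.0

    def test_matches_exhaustive_hypergeometric_enumeration(self):
        p, _ = pooled_fisher_test(50, 10, 10, 50)
        assert p == pytest.approx(fisher_two_sided(50, 10, 10, 50), rel=1e-9)
        for table in [(5, 3, 2, 9), (12, 4, 7, 7), (1, 9, 8, 2)]:
            p, _ = pooled_fisher_test(*table)
            assert p == pytest.approx(fisher_two_sided(*table), rel=1e-9)

    def test_group_swap_keeps_p_and_negates_lfc(self):
        p1, l1 = pooled_fisher_test(40, 12, 9, 33)
        p2, l2 = pooled_fisher_test(9, 33, 40, 12)
        assert p1 == pytest.approx(p2)
        assert l1 == pytest.approx(-l2)

    def test_haldane_correction_on_zero_cells(self):
        _, lfc = pooled_fisher_test(10, 5, 0, 5)
        assert np.isfinite(lfc)


class TestSizeFactors:
    def test_doubled_sample_gets_double_factor(self):
        df = pd.DataFrame({"s1": [10, 20, 30], "s2": [20, 40, 60]})
        f = normalize_library_sizes(df)
        assert f["s2"] / f["s1"] == pytest.approx(2.0)

    def test_identical_columns_give_unit_factors(self):
        df = pd.DataFrame({"s1": [5, 7, 9], "s2": [5, 7, 9]})
        assert normalize_library_sizes(df).tolist() == pytest.approx([1.0, 1.0])

    def test_feature_order_invariance(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.integers(1, 500, (50, 4)), columns=list("abcd"))
        f1 = normalize_library_sizes(df)
        f2 = normalize_library_sizes(df.sample(frac=1, random_state=0))
        assert f1.tolist() == pytest.approx(f2.tolist())

    def test_all_zero_feature_fallback(self):
        df = pd.DataFrame({"s1": [0, 5], "s2": [3, 0]})
        f = normalize_library_sizes(df)
        assert (f > 0).all()


def _peak_table(ip_a, in_a, ip_b, in_b, n_rep=3):
    """Noiseless peak count table from per-group per-peak means."""
    cols, data = [], {}
    for r in range(n_rep):
        data[f"9311_CK_rep{r + 1}_IP"] = ip_a
        data[f"9311_CK_rep{r + 1}_input"] = in_a
        data[f"9311_Cd_rep{r + 1}_IP"] = ip_b
        data[f"9311_Cd_rep{r + 1}_input"] = in_b
    counts = pd.DataFrame(data).astype("int64")
    counts.index = [f"p{i}" for i in range(len(counts))]
    from merip_conjoint.genomic_io import parse_sample_label

    meta = pd.DataFrame({c: parse_sample_label(c) for c in counts.columns}).T
    return CountTable(counts, metadata=meta)


class TestDiffPeaks:
    def test_no_change_is_nde(self):
        table = _peak_table([100, 200], [50, 100], [100, 200], [50, 100])
        res = diff_peaks(table, "9311_CK", "9311_Cd")
        assert (res["direction"] == "NDE").all()
        assert res["log2fc"].abs().max() < 1e-6

    def test_scaling_one_sample_leaves_log2fc_unchanged(self):
        table = _peak_table([100, 400], [50, 100], [400, 400], [50, 100])
        res1 = diff_peaks(table, "9311_CK", "9311_Cd")
        scaled = table.counts.copy()
        scaled["9311_Cd_rep1_IP"] = scaled["9311_Cd_rep1_IP"] * 2
        scaled["9311_Cd_rep1_input"] = scaled["9311_Cd_rep1_input"] * 2
        table2 = CountTable(scaled, metadata=table.metadata)
        res2 = diff_peaks(table2, "9311_CK", "9311_Cd")
        assert res2["log2fc"].tolist() == pytest.approx(
            res1["log2fc"].tolist(), abs=0.05
        )

    def test_fisher_method_recovers_pooled_table_semantics(self):
        # stable background features pin the size factors at 1, so the
        # pooled 2x2 for the first peak matches the direct Fisher call
        stable = [200, 300, 150, 80, 500]
        table = _peak_table(
            [100] + stable, [100] + stable, [400] + stable, [100] + stable,
            n_rep=1,
        )
        res = diff_peaks(table, "9311_CK", "9311_Cd", method="fisher")
        assert res["log2fc"].iloc[0] == pytest.approx(2.0)
        p_expected, _ = pooled_fisher_test(100, 100, 400, 100)
        assert res["pvalue"].iloc[0] == pytest.approx(p_expected)

    def test_unknown_method_rejected(self):
        table = _peak_table([10], [10], [10], [10])
        with pytest.raises(ValueError):
            diff_peaks(table, "9311_CK", "9311_Cd", method="bogus")


def _gene_table(means_a, means_b, n_rep=3, jitter=None):
    data = {}
    for r in range(n_rep):
        ja = jitter[r] if jitter else 0
        data[f"9311_CK_rep{r + 1}"] = np.asarray(means_a) + ja
        data[f"9311_Cd_rep{r + 1}"] = np.asarray(means_b) + ja
    counts = pd.DataFrame(data).astype("int64")
    counts.index = [f"g{i}" for i in range(len(counts))]
    from merip_conjoint.genomic_io import parse_sample_label

    meta = pd.DataFrame({c: parse_sample_label(c) for c in counts.columns}).T
    return CountTable(counts, metadata=meta)


class TestDiffGenes:
    def test_identical_groups_all_nde(self):
        table = _gene_table([100, 250, 30], [100, 250, 30], jitter=[0, 3, 7])
        res = diff_genes(table, "9311_CK", "9311_Cd")
        assert (res["direction"] == "NDE").all()
        assert res["log2fc"].abs().max() < 1e-9

    def test_all_zero_gene_is_nde_with_p_one(self):
        table = _gene_table([0, 100], [0, 100], jitter=[0, 1, 2])
        res = diff_genes(table, "9311_CK", "9311_Cd")
        assert res.loc["g0", "pvalue"] == 1.0
        assert res.loc["g0", "direction"] == "NDE"

    def test_requires_two_samples_per_group(self):
        table = _gene_table([10], [10], n_rep=1)
        with pytest.raises(ValueError):
            diff_genes(table, "9311_CK", "9311_Cd")


class TestCdf:
    def test_three_point_cdf(self):
        (df,) = log2_intensity_cdf({"g": [1.0, 2.0, 3.0]}).values()
        assert df["value"].tolist() == [1.0, 2.0, 3.0]
        assert df["cdf"].tolist() == pytest.approx([1 / 3, 2 / 3, 1.0])

    def test_duplicates_collapse_to_single_step(self):
        (df,) = log2_intensity_cdf({"g": [2.0, 2.0, 5.0, 1.0]}).values()
        assert df["value"].tolist() == [1.0, 2.0, 5.0]
        assert df["cdf"].tolist() == pytest.approx([0.25, 0.75, 1.0])

    def test_empty_group(self):
        (df,) = log2_intensity_cdf({"g": []}).values()
        assert df.empty

    def test_shifted_distribution_lies_right(self):
        rng = np.random.default_rng(8)
        base = rng.normal(0, 1, 500)
        curves = log2_intensity_cdf({"CK": base, "Cd": base + 1.0})
        grid = np.linspace(-2, 2, 9)
        for q in grid:
            ck = np.interp(q, curves["CK"]["value"], curves["CK"]["cdf"])
            cd = np.interp(q, curves["Cd"]["value"], curves["Cd"]["cdf"])
            assert cd <= ck + 1e-9


class TestVolcano:
    def _results(self, rows):
        return pd.DataFrame(
            rows, columns=["log2fc", "pvalue", "fdr"],
            index=[f"f{i}" for i in range(len(rows))],
        )

    def test_all_significant_labeled_when_fewer_than_top_n(self):
        res = self._results([[1.0, 0.001, 0.01]] * 5)
        assert len(volcano_labels(res)) == 5

    def test_extreme_lfc_labeled_even_if_not_significant(self):
        res = self._results([[4.5, 0.5, 0.9], [0.1, 0.5, 0.9]])
        assert volcano_labels(res) == ["f0"]

    def test_lfc_exactly_at_cut_not_labeled(self):
        res = self._results([[4.0, 0.5, 0.9]])
        assert volcano_labels(res) == []


class TestDdct:
    def test_all_equal_ct_gives_unity(self):
        rec = QpcrRecord(20.0, 20.0, 20.0, 20.0)
        assert ddct_relative_expression(rec) == 1.0

    def test_arithmetic_cases(self):
        # dCt treated 4, control 6 -> ddCt -2 -> 2^2 = 4
        rec = QpcrRecord(24.0, 20.0, 26.0, 20.0)
        assert ddct_relative_expression(rec) == pytest.approx(4.0)
        # ddCt = 1 -> 0.5
        rec = QpcrRecord(21.0, 20.0, 20.0, 20.0)
        assert ddct_relative_expression(rec) == pytest.approx(0.5)

    def test_missing_ct_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            QpcrRecord(20.0, None, 20.0, 20.0)

    def test_nonpositive_ct_rejected(self):
        with pytest.raises(ValueError):
            QpcrRecord(20.0, -1.0, 20.0, 20.0)
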