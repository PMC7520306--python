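"""Differential testing, evidence aggregation, candidate selection, ddCt."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from netwalk.validation import (
    aggregate_neglogp,
    ddct_relative_expression,
    differential_test,
    select_candidates,
)


def two_group_frame(sens_rows, res_rows, genes):
    values = np.hstack([np.asarray(sens_rows, float), np.asarray(res_rows, float)])
    n_s = np.asarray(sens_rows).shape[1]
    n_r = np.asarray(res_rows).shape[1]
    cols = [f"s{i}" for i in range(n_s + n_r)]
    expr = pd.DataFrame(values, index=genes, columns=cols)
    labels = pd.Series(["sensitive"] * n_s + ["resistant"] * n_r, index=cols)
    return expr, labels


class TestDifferentialTest:
    def test_identical_groups_give_p_one(self):
        expr, labels = two_group_frame([[1, 2, 3]], [[1, 2, 3]], ["G"])
        res = differential_test(expr, labels, ["G"])
        assert res.loc["G", "p"] == pytest.approx(1.0)
        assert res.loc["G", "direction"] == "0"

    def test_matches_textbook_welch_formula(self):
        # hand-built Welch statistic with Welch-Satterthwaite df, then the
        # t survival function -- independent of scipy's ttest_ind path
        a, b = np.array([5.0, 6, 7, 8]), np.array([1.0, 2, 3, 4])
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        t = (a.mean() - b.mean()) / math.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
        p_expected = 2 * stats.t.sf(abs(t), df)

        expr, labels = two_group_frame([a.tolist()], [b.tolist()], ["G"])
        res = differential_test(expr, labels, ["G"])
        assert res.loc["G", "p"] == pytest.approx(p_expected, rel=1e-12)
        assert res.loc["G", "direction"] == "+"

    def test_label_swap_keeps_p_flips_direction(self, rng):
        values = rng.normal(size=(3, 12))
        values[0, :6] += 1.5
        genes = ["A", "B", "C"]
        cols = [f"s{i}" for i in range(12)]
        expr = pd.DataFrame(values, index=genes, columns=cols)
        fwd = pd.Series(["sensitive"] * 6 + ["resistant"] * 6, index=cols)
        rev = fwd.map({"sensitive": "resistant", "resistant": "sensitive"})
        res_f = differential_test(expr, fwd, genes)
        res_r = differential_test(expr, rev, genes)
        assert res_f["p"].tolist() == pytest.approx(res_r["p"].tolist())
        flip = {"+": "-", "-": "+", "0": "0"}
        assert [flip[d] for d in res_f["direction"]] == res_r["direction"].tolist()

    def test_small_group_rejected(self):
        expr, labels = two_group_frame([[1, 2, 3]], [[1, 2, 3]], ["G"])
        labels.iloc[:2] = "resistant"  # sensitive group left with 1 sample
        with pytest.raises(ValueError, match=">= 2 samples"):
            differential_test(expr, labels, ["G"])

    def test_absent_gene_recorded_not_raised(self):
        expr, labels = two_group_frame([[1, 2, 3]], [[4, 5, 6]], ["G"])
        res = differential_test(expr, labels, ["G", "MISSING"])
        assert not res.loc["MISSING", "tested"]
        assert math.isnan(res.loc["MISSING", "p"])
        assert res.loc["G", "tested"]

    def test_wilcoxon_option_matches_scipy(self, rng):
        a, b = rng.normal(1, 1, 8), rng.normal(0, 1, 9)
        expr, labels = two_group_frame([a.tolist()], [b.tolist()], ["G"])
        res = differential_test(expr, labels, ["G"], method="wilcoxon")
        _, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        assert res.loc["G", "p"] == pytest.approx(p)


def report_from(pairs):
    """Build a differential-test-shaped report from {gene: p}."""
    return pd.DataFrame(
        {"p": pd.Series(pairs), "direction": "+", "tested": True}
    ).rename_axis("gene")


class TestAggregateNeglogp:
    def test_p_point_one_twice_means_one(self):
        reports = {"d1": report_from({"G": 0.1}), "d2": report_from({"G": 0.1})}
        gene_df, _ = aggregate_neglogp(reports, ["G"])
        assert gene_df.loc["G", "mean_neglog10p"] == pytest.approx(1.0)
        assert gene_df.loc["G", "coverage"] == 2

    def test_p_one_everywhere_means_zero(self):
        reports = {"d1": report_from({"G": 1.0}), "d2": report_from({"G": 1.0})}
        gene_df, _ = aggregate_neglogp(reports, ["G"])
        assert gene_df.loc["G", "mean_neglog10p"] == pytest.approx(0.0)

    def test_hand_computed_mean(self):
        # (-log10(0.01) - log10(0.1)) / 2 = (2 + 1) / 2
        reports = {"d1": report_from({"G": 0.01}), "d2": report_from({"G": 0.1})}
        gene_df, _ = aggregate_neglogp(reports, ["G"])
        assert gene_df.loc["G", "mean_neglog10p"] == pytest.approx(1.5)

    def test_untested_gene_gets_empty_value(self):
        reports = {"d1": report_from({"G": 0.5})}
        gene_df, _ = aggregate_neglogp(reports, ["G", "ABSENT"])
        assert gene_df.loc["ABSENT", "coverage"] == 0
        assert math.isnan(gene_df.loc["ABSENT", "mean_neglog10p"])

    def test_dataset_order_invariance(self, rng):
        ps = {f"G{i}": float(p) for i, p in enumerate(rng.uniform(0.01, 1, 5))}
        qs = {f"G{i}": float(p) for i, p in enumerate(rng.uniform(0.01, 1, 5))}
        genes = list(ps)
        a, _ = aggregate_neglogp({"x": report_from(ps), "y": report_from(qs)}, genes)
        b, _ = aggregate_neglogp({"y": report_from(qs), "x": report_from(ps)}, genes)
        assert a["mean_neglog10p"].tolist() == pytest.approx(b["mean_neglog10p"].tolist())

    def test_scaling_all_p_by_ten_shifts_mean_by_one(self):
        ps = {"A": 0.001, "B": 0.02, "C": 0.1}
        before, _ = aggregate_neglogp({"d": report_from(ps)}, list(ps))
        scaled = {g: p * 10 for g, p in ps.items()}
        after, _ = aggregate_neglogp({"d": report_from(scaled)}, list(ps))
        shift = before["mean_neglog10p"] - after["mean_neglog10p"]
        assert shift.tolist() == pytest.approx([1.0, 1.0, 1.0])

    def test_group_means_average_member_means(self):
        reports = {"d": report_from({"A": 0.1, "B": 0.001})}
        _, groups = aggregate_neglogp(reports, ["A", "B"],
                                      groups={"grp": ["A", "B"]})
        assert groups["grp"] == pytest.approx((1 + 3) / 2)


class TestSelectCandidates:
    def ranking(self, genes):
        return [(g, 1.0 - 0.01 * i) for i, g in enumerate(genes)]

    def test_disjoint_tops_give_six_candidates(self):
        lists = {
            "FO-G": self.ranking(["A", "B", "x"]),
            "HFC-G": self.ranking(["C", "D", "y"]),
            "HO-G": self.ranking(["E", "F", "z"]),
        }
        sel = select_candidates(lists, k=2)
        assert len(sel.union) == 6
        assert sel.per_group["FO-G"] == ["A", "B"]

    def test_k_zero_selects_nothing(self):
        sel = select_candidates({"g": self.ranking(["A"])}, k=0)
        assert sel.union == [] and sel.per_group["g"] == []

    def test_shared_top_gene_deduplicated(self):
        lists = {"g1": self.ranking(["A", "B"]), "g2": self.ranking(["A", "C"])}
        sel = select_candidates(lists, k=2)
        assert sel.union == ["A", "B", "C"]

    def test_short_list_taken_whole_with_warning(self):
        with pytest.warns(UserWarning, match="only 1"):
            sel = select_candidates({"g": self.ranking(["A"])}, k=3)
        assert sel.per_group["g"] == ["A"]

    def test_union_size_accounts_for_duplicates(self, rng):
        genes = [f"G{i}" for i in range(12)]
        lists = {}
        for name in ("a", "b", "c"):
            order = list(rng.permutation(genes))
            lists[name] = self.ranking(order)
        k = 3
        sel = select_candidates(lists, k=k)
        tops = [g for name in lists for g in sel.per_group[name]]
        duplicates = len(tops) - len(set(tops))
        assert len(sel.union) == k * len(lists) - duplicates


class TestDdct:
    def test_zero_ddct_gives_unit_fold_change(self):
        assert ddct_relative_expression(20, 15, 22, 17) == pytest.approx(1.0)

    def test_one_cycle_halves_expression(self):
        assert ddct_relative_expression(21, 15, 22, 17) == pytest.approx(0.5)

    def test_hand_arithmetic_example(self):
        # ddCt = (24-18) - (26-18) = -2 -> 2^2 = 4
        assert ddct_relative_expression(24, 18, 26, 18) == pytest.approx(4.0)

    @given(a=st.floats(-50, 50), b=st.floats(-50, 50))
    def test_matched_conditions_always_unit(self, a, b):
        assert ddct_relative_expression(a, b, a, b) == pytest.approx(1.0)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            ddct_relative_expression(float("nan"), 1, 2, 3)
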