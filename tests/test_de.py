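"""Differential-expression statistics: multiplicity corrections against
independent oracles, t-test conventions, threshold gates, merge logic."""

import numpy as np
import pandas as pd
import pytest

from cernet.de import (
    ThresholdPolicy,
    adjust_bh,
    adjust_holm,
    call_de,
    differential_test,
    merge_comparisons,
    signed_fold_change,
)
from cernet.io import ExpressionMatrix

from oracles import bh_textbook, holm_textbook


def _two_group(a_vals, b_vals):
    values = np.array([list(a_vals) + list(b_vals)], dtype=float)
    samples = [f"a{i}" for i in range(len(a_vals))] + [f"b{i}" for i in range(len(b_vals))]
    cond = {s: ("A" if s.startswith("a") else "B") for s in samples}
    return ExpressionMatrix("mRNA", pd.DataFrame(values, index=["f"], columns=samples), cond)


class TestAdjustments:
    def test_bh_worked_examples(self):
        np.testing.assert_allclose(adjust_bh([0.05]), [0.05])
        np.testing.assert_allclose(adjust_bh([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_holm_worked_examples(self):
        np.testing.assert_allclose(adjust_holm([0.01, 0.04]), [0.02, 0.04])
        np.testing.assert_allclose(adjust_holm([0.2]), [0.2])

    def test_bounds(self, rng):
        p = rng.uniform(size=200)
        for adj in (adjust_bh, adjust_holm):
            q = adj(p)
            assert np.all(q >= p - 1e-15)
            assert np.all(q <= 1.0)

    @pytest.mark.parametrize("n", [1, 2, 7, 50, 400])
    def test_matches_textbook_oracles(self, n, rng):
        for _ in range(20):
            p = rng.uniform(size=n)
            np.testing.assert_allclose(adjust_bh(p), bh_textbook(p), atol=1e-12)
            np.testing.assert_allclose(adjust_holm(p), holm_textbook(p), atol=1e-12)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=300)
        np.testing.assert_allclose(
            adjust_bh(p), multipletests(p, method="fdr_bh")[1], atol=1e-12
        )
        np.testing.assert_allclose(
            adjust_holm(p), multipletests(p, method="holm")[1], atol=1e-12
        )

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.2])
        with pytest.raises(ValueError):
            adjust_holm([-0.1])


class TestDifferentialTest:
    def test_fold_change_sign_convention(self):
        fc = signed_fold_change(np.array([1.0, -1.0, 0.0, 2.0]))
        np.testing.assert_allclose(fc, [2.0, -2.0, 1.0, 4.0])
        assert not np.any((fc > -1.0) & (fc < 1.0))

    def test_doubling_means(self):
        res = differential_test(_two_group([5.0, 5.1, 4.9], [6.0, 6.1, 5.9]), "A", "B")
        assert res.loc[0, "log2fc"] == pytest.approx(1.0)
        assert res.loc[0, "fold_change"] == pytest.approx(2.0)

    def test_halving_means_negative(self):
        res = differential_test(_two_group([6.0, 6.1, 5.9], [5.0, 5.1, 4.9]), "A", "B")
        assert res.loc[0, "fold_change"] == pytest.approx(-2.0)

    def test_identical_groups_p_one(self):
        res = differential_test(_two_group([1, 2, 3], [1, 2, 3]), "A", "B")
        assert res.loc[0, "p_raw"] == 1.0
        assert not res.loc[0, "degenerate"]

    def test_zero_variance_unequal_means_degenerate(self):
        res = differential_test(_two_group([1, 1, 1], [2, 2, 2]), "A", "B")
        assert res.loc[0, "p_raw"] == 0.0
        assert bool(res.loc[0, "degenerate"])

    def test_matches_scipy_pooled_and_welch(self, rng):
        from scipy import stats

        a = rng.normal(5, 1, (30, 3))
        b = rng.normal(6, 2, (30, 3))
        samples = ["a0", "a1", "a2", "b0", "b1", "b2"]
        cond = {s: s[0].upper() for s in samples}
        m = ExpressionMatrix(
            "mRNA",
            pd.DataFrame(np.hstack([a, b]), index=[f"f{i}" for i in range(30)], columns=samples),
            cond,
        )
        pooled = differential_test(m, "A", "B")
        welch = differential_test(m, "A", "B", welch=True)
        ref_pooled = stats.ttest_ind(b, a, axis=1)
        ref_welch = stats.ttest_ind(b, a, axis=1, equal_var=False)
        np.testing.assert_allclose(pooled["p_raw"], ref_pooled.pvalue, atol=1e-12)
        np.testing.assert_allclose(welch["p_raw"], ref_welch.pvalue, atol=1e-12)

    def test_rejects_missing_condition(self):
        with pytest.raises(KeyError):
            differential_test(_two_group([1, 2], [3, 4]), "A", "Z")


class TestCallDE:
    def _stats(self, fold_changes, p_raws):
        lfc = np.log2(np.abs(fold_changes)) * np.sign(fold_changes)
        return pd.DataFrame(
            {
                "feature_id": [f"f{i}" for i in range(len(p_raws))],
                "log2fc": lfc,
                "fold_change": fold_changes,
                "p_raw": p_raws,
            }
        )

    def test_passes_both_gates(self):
        calls = call_de(self._stats(np.array([2.5]), [0.01]), ThresholdPolicy(), "mRNA", "AvsCtrl")
        assert calls.loc[0, "direction"] == "up"

    def test_fc_gate_blocks(self):
        calls = call_de(self._stats(np.array([1.9]), [0.001]), ThresholdPolicy(), "mRNA", "AvsCtrl")
        assert calls.loc[0, "direction"] == "not_de"

    def test_mirna_uses_lower_fc_threshold(self):
        calls = call_de(self._stats(np.array([1.6]), [0.01]), ThresholdPolicy(), "miRNA", "AvsCtrl")
        assert calls.loc[0, "direction"] == "up"

    def test_circrna_gates_on_raw_p(self):
        # p_raw 0.03 adjusts above alpha in a family of 3, but circRNA
        # policy gates on the raw value
        stats_df = self._stats(np.array([3.0, 1.0, 1.0]), [0.03, 0.8, 0.9])
        circ = call_de(stats_df, ThresholdPolicy(), "circRNA", "AvsCtrl")
        mrna = call_de(stats_df, ThresholdPolicy(), "mRNA", "AvsCtrl")
        assert circ.loc[0, "direction"] == "up"
        assert mrna.loc[0, "direction"] == "not_de"

    def test_adjusted_p_reported_and_monotone(self):
        calls = call_de(
            self._stats(np.array([2.5, -2.5, 1.1]), [0.01, 0.02, 0.9]),
            ThresholdPolicy(), "mRNA", "AvsCtrl",
        )
        assert np.all(calls["p_adj"] >= calls["p_raw"] - 1e-15)

    def test_rejects_unknown_species(self):
        with pytest.raises(ValueError):
            call_de(self._stats(np.array([2.0]), [0.01]), ThresholdPolicy(), "tRNA", "AvsCtrl")


class TestMerge:
    def _calls(self, rows, comparison):
        df = pd.DataFrame(
            rows, columns=["feature_id", "fold_change", "p_raw", "p_adj", "direction"]
        )
        df["log2fc"] = np.log2(df["fold_change"].abs()) * np.sign(df["fold_change"])
        df["species"] = "lncRNA"
        df["comparison"] = comparison
        return df

    def test_direction_consistent_intersection(self):
        a = self._calls(
            [("x", 2.5, 0.01, 0.02, "up"), ("y", 2.5, 0.01, 0.02, "up"),
             ("z", -3.0, 0.01, 0.02, "down")],
            "AvsCtrl",
        )
        b = self._calls(
            [("x", 3.0, 0.02, 0.03, "up"), ("y", -2.5, 0.01, 0.02, "down"),
             ("w", 2.0, 0.01, 0.02, "up")],
            "BvsCtrl",
        )
        merged = merge_comparisons(a, b)
        assert list(merged["feature_id"]) == ["x"]  # y conflicts, z/w one-sided
        assert merged.loc[0, "direction"] == "up"
        assert merged.loc[0, "comparison"] == "merged"

    def test_merged_is_subset_of_both(self, rng):
        def random_calls(comp):
            rows = []
            for i in range(50):
                fc = float(rng.choice([-3.0, -2.5, 1.2, 2.5, 3.0]))
                de = abs(fc) >= 2 and rng.uniform() < 0.6
                rows.append(
                    (f"f{i}", fc, 0.01, 0.02, ("up" if fc > 0 else "down") if de else "not_de")
                )
            return self._calls(rows, comp)

        a, b = random_calls("AvsCtrl"), random_calls("BvsCtrl")
        merged = merge_comparisons(a, b)
        for calls in (a, b):
            de_ids = set(calls.loc[calls["direction"] != "not_de", "feature_id"])
            assert set(merged["feature_id"]) <= de_ids
        assert len(merged) <= min(
            (a["direction"] != "not_de").sum(), (b["direction"] != "not_de").sum()
        )

    def test_conservative_statistics(self):
        a = self._calls([("x", 4.0, 0.001, 0.002, "up")], "AvsCtrl")
        b = self._calls([("x", 2.5, 0.01, 0.03, "up")], "BvsCtrl")
        merged = merge_comparisons(a, b)
        assert merged.loc[0, "fold_change"] == pytest.approx(2.5)
        assert merged.loc[0, "p_adj"] == pytest.approx(0.03)

    def test_rejects_species_mismatch(self):
        a = self._calls([("x", 2.5, 0.01, 0.02, "up")], "AvsCtrl")
        b = self._calls([("x", 2.5, 0.01, 0.02, "up")], "BvsCtrl")
        b["species"] = "mRNA"
        with pytest.raises(ValueError, match="species"):
            merge_comparisons(a, b)
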