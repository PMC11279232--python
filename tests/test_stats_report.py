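import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from spotscreen.stats_report import (
    ContingencyTable,
    fisher_exact,
    g_test,
    proportion_summary,
    round_half_up,
    venn_counts,
)


def g_oracle(table):
    """Direct evaluation of 2*sum(o*ln(o/e)) with explicit loops."""
    table = np.asarray(table, dtype=float)
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    total = table.sum()
    g = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            o = table[i, j]
            if o > 0:
                g += o * math.log(o / (row[i] * col[j] / total))
    return 2.0 * g


class TestGTest:
    def test_perfect_independence(self):
        res = g_test([[10, 10], [10, 10]])
        assert res.g == 0.0
        assert res.p_value == 1.0

    def test_formula_oracle(self):
        res = g_test([[20, 146], [5, 161]])
        assert res.g == pytest.approx(g_oracle([[20, 146], [5, 161]]), abs=1e-9)

    def test_hand_evaluated_diagonal_table(self):
        res = g_test([[0, 10], [10, 0]])
        assert res.g == pytest.approx(40.0 * math.log(2.0), abs=1e-9)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            g_test([[0, 0], [5, 5]])

    def test_degrees_of_freedom(self):
        res = g_test([[5, 6, 7], [8, 9, 10]])
        assert res.df == 2

    def test_matches_scipy_log_likelihood(self):
        table = [[23, 41, 12], [7, 30, 19]]
        res = g_test(table)
        g, p, df, _ = stats.chi2_contingency(
            np.asarray(table), lambda_="log-likelihood", correction=False
        )
        assert res.g == pytest.approx(g, rel=1e-12)
        assert res.p_value == pytest.approx(p, rel=1e-12)

    def test_agrees_with_pearson_in_large_count_limit(self):
        # near-independent tables, all cells >= 500: margin-preserving
        # perturbation of an exact-independence table
        rng = np.random.default_rng(0)
        for _ in range(5):
            row = rng.integers(1500, 3000, size=2).astype(float)
            col = rng.integers(1500, 3000, size=2).astype(float)
            expected = np.outer(row, col) / col.sum()
            d = float(rng.integers(20, 60))
            table = expected + np.array([[d, -d], [-d, d]])
            assert np.all(table >= 500)
            g = g_test(table).g
            chi2 = stats.chi2_contingency(table, correction=False)[0]
            assert abs(g - chi2) / chi2 < 0.01

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.integers(1, 200), min_size=4, max_size=4))
    def test_matches_direct_formula(self, cells):
        table = np.array(cells, dtype=float).reshape(2, 2)
        assert g_test(table).g == pytest.approx(g_oracle(table), abs=1e-9)


def fisher_right_oracle(a, b, c, d):
    """Hypergeometric enumeration: P(first cell >= a) with fixed margins."""
    r1, c1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    probs = {x: stats.hypergeom.pmf(x, n, c1, r1) for x in range(lo, hi + 1)}
    return sum(p for x, p in probs.items() if x >= a)


def fisher_two_sided_oracle(a, b, c, d):
    r1, c1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    probs = {x: stats.hypergeom.pmf(x, n, c1, r1) for x in range(lo, hi + 1)}
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-10))


class TestFisherExact:
    def test_right_sided_hand_example(self):
        # enumeration gives 17/70 for [[3,1],[1,3]]
        assert fisher_exact([[3, 1], [1, 3]], side="right") == pytest.approx(
            17.0 / 70.0
        )

    def test_degenerate_margin_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[0, 0], [3, 4]])

    def test_non_2x2_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[1, 2, 3], [4, 5, 6]])

    def test_right_p_at_least_observed_probability(self):
        a, b, c, d = 5, 2, 3, 7
        p_obs = stats.hypergeom.pmf(a, a + b + c + d, a + c, a + b)
        assert fisher_exact([[a, b], [c, d]], side="right") >= p_obs - 1e-12

    def test_two_sided_at_least_right_in_right_tail(self):
        table = [[9, 1], [2, 8]]  # observed lies in the right tail
        assert fisher_exact(table, side="two_sided") >= fisher_exact(
            table, side="right"
        )

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 8), st.integers(0, 8), st.integers(0, 8),
           st.integers(0, 8))
    def test_matches_enumeration(self, a, b, c, d):
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            return
        table = [[a, b], [c, d]]
        assert fisher_exact(table, side="right") == pytest.approx(
            fisher_right_oracle(a, b, c, d), abs=1e-9
        )
        assert fisher_exact(table, side="two_sided") == pytest.approx(
            fisher_two_sided_oracle(a, b, c, d), abs=1e-9
        )


class TestRounding:
    def test_half_up(self):
        assert round_half_up(4.785, 2) == 4.79
        assert round_half_up(93.75, 1) == 93.8
        assert round_half_up(0.25, 1) == 0.3


class TestProportionSummary:
    def flags(self, positives, total, medium="LM17"):
        return pd.DataFrame(
            {
                "medium": [medium] * total,
                "antifungal": [True] * positives + [False] * (total - positives),
            }
        )

    def test_two_decimal_overall(self):
        out = proportion_summary(self.flags(49, 1022), "antifungal", decimals=2)
        pct = out.set_index("class").loc[True, "percent"]
        assert pct == 4.79

    def test_one_decimal_majority_class(self):
        df = pd.DataFrame({"cls": ["neutral"] * 2310 + ["other"] * 153})
        out = proportion_summary(df, "cls", decimals=1)
        assert out.set_index("class").loc["neutral", "percent"] == 93.8

    def test_zero_count_class_absent_from_rows(self):
        out = proportion_summary(self.flags(0, 10), "antifungal", decimals=1)
        assert list(out["class"]) == [False]
        assert out["percent"].iloc[0] == 100.0

    def test_grouped_output(self):
        df = pd.concat(
            [self.flags(2, 10, "LM17"), self.flags(5, 20, "PCA")],
            ignore_index=True,
        )
        out = proportion_summary(df, "antifungal", by="medium", decimals=1)
        lm = out[(out["medium"] == "LM17") & (out["class"] == True)]  # noqa: E712
        assert lm["percent"].iloc[0] == 20.0
        assert lm["denominator"].iloc[0] == 10

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            proportion_summary(pd.DataFrame({"x": []}), "x")

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.sampled_from(["a", "b", "c"]), min_size=1, max_size=200),
           st.integers(1, 2))
    def test_percentages_sum_to_100_within_rounding(self, labels, decimals):
        out = proportion_summary(pd.DataFrame({"x": labels}), "x",
                                 decimals=decimals)
        slack = 0.5 * 10 ** (-decimals) * len(out)
        assert out["percent"].sum() == pytest.approx(100.0, abs=slack + 1e-9)


class TestVennCounts:
    def test_all_triple_overlap(self):
        sets = {"A": {1, 2}, "B": {1, 2}, "C": {1, 2}}
        counts = venn_counts(sets)
        assert counts[("A", "B", "C")] == 2
        assert sum(v for k, v in counts.items() if k != ("A", "B", "C")) == 0

    def test_disjoint_singletons(self):
        counts = venn_counts({"A": {1}, "B": {2}, "C": {3}})
        assert counts[("A",)] == counts[("B",)] == counts[("C",)] == 1
        assert counts[("A", "B")] == 0

    def test_partition_property(self):
        rng = np.random.default_rng(7)
        sets = {
            name: set(rng.choice(100, size=rng.integers(5, 40), replace=False))
            for name in "ABC"
        }
        counts = venn_counts(sets)
        assert sum(counts.values()) == len(set().union(*sets.values()))

    def test_wrong_set_count_rejected(self):
        with pytest.raises(ValueError):
            venn_counts({"A": {1}})


def test_contingency_table_validation():
    with pytest.raises(ValueError):
        ContingencyTable(["r"], ["c1", "c2"], np.array([[1.0, -2.0]]))
    table = ContingencyTable(["r1", "r2"], ["c1"], np.array([[1.0], [2.0]]))
    assert table.to_frame().shape == (2, 1)
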