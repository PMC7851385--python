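"""Recurrence testing, FDR, Fisher/Wilcoxon and subgroup burden summaries."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from rarescreen.burden import (
    bh_adjust,
    binomial_recurrence_test,
    fisher_exact_2x2,
    group_burden_summary,
    lengthwise_null_rates,
    recurrence_table,
    wilcoxon_rank_sum,
)


def _binom_tail_oracle(k, n, rate):
    """Brute-force summation of the binomial mass from k to n."""
    return sum(
        comb(n, j) * rate**j * (1 - rate) ** (n - j) for j in range(k, n + 1)
    )


class TestBinomialRecurrence:
    def test_zero_carriers_certain(self):
        assert binomial_recurrence_test(0, 259, 1e-4) == 1.0

    def test_all_carriers_closed_form(self):
        assert binomial_recurrence_test(5, 5, 0.3) == pytest.approx(0.3**5, rel=1e-12)

    def test_matches_summation_oracle_at_study_scale(self):
        p = binomial_recurrence_test(3, 259, 1e-4)
        assert p == pytest.approx(_binom_tail_oracle(3, 259, 1e-4), abs=1e-12)

    @given(
        n=st.integers(1, 1000),
        k_frac=st.floats(0, 1),
        rate=st.floats(0, 1),
    )
    def test_equals_one_minus_cdf_by_naive_summation(self, n, k_frac, rate):
        k = int(round(k_frac * n))
        p = binomial_recurrence_test(k, n, rate)
        assert p == pytest.approx(_binom_tail_oracle(k, n, rate), abs=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            binomial_recurrence_test(5, 4, 0.1)
        with pytest.raises(ValueError):
            binomial_recurrence_test(1, 4, 1.5)


def _bh_oracle(p, m):
    """Naive per-rank formula with an explicit running minimum from the top."""
    order = np.argsort(p, kind="stable")
    raw = [p[order[i]] * m / (i + 1) for i in range(len(p))]
    adj = [min(min(raw[i:]), 1.0) for i in range(len(p))]
    out = np.empty(len(p))
    for i, o in enumerate(order):
        out[o] = adj[i]
    return out


class TestBHAdjust:
    def test_published_recurrence_fdr_values(self):
        # four tabulated gene p-values adjusted against m=2944 screened genes
        p = [9.51e-6, 9.08e-5, 3.67e-4, 7.39e-4]
        adjusted = bh_adjust(p, m=2944)
        assert np.round(adjusted, 3).tolist() == [0.028, 0.134, 0.360, 0.544]

    def test_single_p_with_m_one_unchanged(self):
        assert bh_adjust([0.04], m=1)[0] == pytest.approx(0.04)

    def test_m_smaller_than_tests_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 0.2], m=1)

    @given(
        p=st.lists(st.floats(0, 1), min_size=1, max_size=20),
        extra=st.integers(0, 3000),
    )
    def test_matches_running_minimum_oracle_and_monotone(self, p, extra):
        m = len(p) + extra
        adjusted = bh_adjust(p, m=m)
        assert adjusted == pytest.approx(_bh_oracle(np.asarray(p), m))
        ranked = adjusted[np.argsort(p, kind="stable")]
        assert all(a <= b + 1e-15 for a, b in zip(ranked, ranked[1:]))

    @given(p=st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_never_decreases_any_value_at_m_equal_len(self, p):
        adjusted = bh_adjust(p, m=len(p))
        assert np.all(adjusted >= np.asarray(p) - 1e-15)


def _fisher_enumeration_oracle(a, b, c, d):
    """Exhaustive two-sided Fisher: sum hypergeometric probabilities of all
    tables with the observed margins that are no more probable."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    def prob(x):
        return (
            comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)
        )
    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        if prob(x) <= p_obs * (1 + 1e-9):
            total += prob(x)
    return min(1.0, total)


class TestFisher:
    def test_published_carrier_contrast(self):
        # 5 of 136 rare-CNV-group vs 6 of 123 no-rare-CNV carriers
        assert fisher_exact_2x2([[5, 131], [6, 117]]) == pytest.approx(0.76, abs=5e-3)

    def test_empty_carrier_rows_give_one(self):
        assert fisher_exact_2x2([[0, 10], [0, 10]]) == 1.0

    @given(
        a=st.integers(0, 6), b=st.integers(0, 6),
        c=st.integers(0, 6), d=st.integers(0, 6),
    )
    def test_matches_enumeration_for_small_margins(self, a, b, c, d):
        if a + b == 0 or c + d == 0:
            return
        p = fisher_exact_2x2([[a, b], [c, d]])
        assert p == pytest.approx(_fisher_enumeration_oracle(a, b, c, d), rel=1e-9)

    def test_symmetric_under_row_and_column_swaps(self):
        t = [[5, 131], [6, 117]]
        p = fisher_exact_2x2(t)
        assert fisher_exact_2x2([t[1], t[0]]) == pytest.approx(p)
        assert fisher_exact_2x2([[5, 6], [131, 117]][::-1]) == pytest.approx(
            fisher_exact_2x2([[5, 6], [131, 117]])
        )


class TestWilcoxonRankSum:
    def test_identical_samples_two_sided_is_one(self):
        assert wilcoxon_rank_sum([1, 2, 3], [1, 2, 3]) == 1.0

    def test_extreme_small_sample_enumeration(self):
        # x={1,2}, y={3,4}: rank-sum of x is minimal in 1 of C(4,2)=6 splits
        assert wilcoxon_rank_sum([1, 2], [3, 4], "less") == pytest.approx(1 / 6)

    def test_asymptotic_close_to_enumeration_at_boundary_size(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 6)
        y = rng.normal(0.5, 1, 6)
        exact = wilcoxon_rank_sum(list(x), list(y), "less")  # n=12: enumeration
        approx = float(
            stats.mannwhitneyu(x, y, alternative="less", method="asymptotic")[1]
        )
        assert abs(exact - approx) < 0.01

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestGroupBurden:
    def test_all_zero_burdens(self):
        out = group_burden_summary([0, 0, 0, 0], ["g", "g", "h", "h"], seed=0)
        for s in out:
            assert s.mean_burden == 0.0
            assert (s.ci_low, s.ci_high) == (0.0, 0.0)
            assert s.p_vs_complement == 1.0

    def test_multi_class_burden_definition(self):
        # one pathogenic CNV plus one clinically relevant SNV = burden 2
        burdens = [2, 0, 0, 1]
        out = group_burden_summary(burdens, ["x", "x", "y", "y"], seed=0)
        by = {s.group: s for s in out}
        assert by["x"].mean_burden == pytest.approx(1.0)

    def test_ci_brackets_mean_and_p_reproducible(self):
        rng = np.random.default_rng(4)
        burdens = rng.poisson(0.5, 60)
        groups = np.where(rng.random(60) < 0.5, "a", "b")
        out1 = group_burden_summary(burdens, groups, n_perm=2000, seed=9)
        out2 = group_burden_summary(burdens, groups, n_perm=2000, seed=9)
        for s1, s2 in zip(out1, out2):
            assert s1 == s2
            assert s1.ci_low <= s1.mean_burden <= s1.ci_high
            assert 1 / 2001 <= s1.p_vs_complement <= 1.0

    def test_permutation_p_uniform_under_null(self):
        """Type-I calibration: null permutation p-values are uniform
        (Kolmogorov–Smirnov at alpha=0.01 over 200 replicates)."""
        rng = np.random.default_rng(12)
        pvals = []
        for _ in range(200):
            burdens = rng.normal(0, 1, 40)
            groups = np.array(["a"] * 20 + ["b"] * 20)
            out = group_burden_summary(
                burdens, groups, n_boot=1000, n_perm=999, seed=int(rng.integers(2**31))
            )
            pvals.append(out[0].p_vs_complement)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_burden_summary([1.0], [], seed=0)


class TestRecurrenceTable:
    def test_table_ranks_and_fdr_consistent(self):
        counts = {"A": 3, "B": 2, "C": 2}
        rates = {"A": 1e-4, "B": 1e-4, "C": 5e-4}
        table = recurrence_table(counts, n=259, null_rates=rates, m=3000)
        assert list(table["rank"]) == [1, 2, 3]
        assert (table["fdr"] >= table["p_binomial"] - 1e-15).all()
        oracle = _binom_tail_oracle(3, 259, 1e-4)
        assert table.loc[0, "p_binomial"] == pytest.approx(oracle, abs=1e-12)

    def test_lengthwise_null_rate_helper(self):
        genes = pd.DataFrame(
            {"symbol": ["A", "B"], "coding_length_kb": [1.0, 3.0]}
        )
        rates = lengthwise_null_rates(genes, total_qualifying_carriers=40, n=100)
        assert rates["A"] == pytest.approx(40 * 0.25 / 100)
        assert rates["B"] == pytest.approx(40 * 0.75 / 100)

    def test_missing_rate_rejected(self):
        with pytest.raises(ValueError):
            recurrence_table({"A": 1}, n=10, null_rates={"B": 0.1}, m=10)
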