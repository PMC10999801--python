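"""Summary statistics, paired tests, Bonferroni, frequency tables, reports."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from ielquant.stats import (
    NOT_ASSESSED,
    WILCOXON_PRATT_APPROX,
    WILCOXON_PRATT_EXACT,
    PairedSample,
    bonferroni,
    frequency_table,
    frequency_table_from_counts,
    included_after_exclusions,
    paired_t,
    pairwise_comparison_report,
    summarize,
    wilcoxon_pratt,
)


def sample_from_diffs(diffs):
    diffs = np.asarray(diffs, dtype=float)
    return PairedSample(list(range(len(diffs))), diffs, np.zeros_like(diffs))


def brute_force_wilcoxon_pratt(diffs):
    """Independent oracle: full 2^m enumeration over nonzero-difference signs."""
    diffs = np.asarray(diffs, dtype=float)
    ranks = sps.rankdata(np.abs(diffs))
    nz = ranks[diffs != 0]
    signs_obs = diffs[diffs != 0] > 0
    w_obs = nz[signs_obs].sum()
    m = len(nz)
    if m == 0:
        return 1.0
    ws = []
    for signs in itertools.product([0, 1], repeat=m):
        ws.append(sum(r for r, s in zip(nz, signs) if s))
    ws = np.asarray(ws)
    p_le = np.mean(ws <= w_obs + 1e-9)
    p_ge = np.mean(ws >= w_obs - 1e-9)
    return min(1.0, 2 * min(p_le, p_ge))


class TestSummarize:
    def test_constant_vector_has_zero_width_ci(self):
        s = summarize([4.0, 4.0, 4.0])
        assert s.ci_low == s.ci_high == s.mean == 4.0

    def test_closed_form_oracle(self):
        v = np.array([1.0, 2, 3, 4, 5])
        s = summarize(v)
        sem = v.std(ddof=1) / np.sqrt(5)
        tq = sps.t.ppf(0.975, 4)
        assert s.mean == 3 and (s.min, s.max) == (1, 5)
        assert s.ci_low == pytest.approx(3 - tq * sem, abs=1e-12)
        assert s.ci_high == pytest.approx(3 + tq * sem, abs=1e-12)

    def test_single_value_flags_undefined_ci(self):
        s = summarize([7.0])
        assert s.mean == 7.0 and not s.ci_defined and np.isnan(s.ci_low)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize([])


class TestPairedT:
    def test_identical_pairs_give_t0_p1(self):
        r = paired_t(PairedSample([1, 2, 3], [1.0, 2, 3], [1.0, 2, 3]))
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_constant_nonzero_difference_is_degenerate(self):
        with pytest.raises(ValueError, match="zero variance"):
            paired_t(PairedSample([1, 2], [2.0, 3.0], [1.0, 2.0]))

    def test_closed_form_oracle(self):
        r = paired_t(sample_from_diffs([1.0, 2.0, 3.0]))
        assert r.statistic == pytest.approx(2 * np.sqrt(3), abs=1e-12)
        assert r.p_value == pytest.approx(2 * sps.t.sf(2 * np.sqrt(3), 2), abs=1e-10)

    def test_sign_flip_antisymmetry(self):
        x = np.array([3.0, 1.0, 4.0, 1.5])
        y = np.array([2.0, 2.0, 2.0, 2.0])
        a = paired_t(PairedSample(range(4), x, y))
        b = paired_t(PairedSample(range(4), y, x))
        assert a.statistic == pytest.approx(-b.statistic)
        assert a.p_value == pytest.approx(b.p_value)

    def test_missing_pairs_excluded_and_counted(self):
        x = np.array([1.0, 2.0, np.nan, 4.0])
        y = np.array([0.0, 1.0, 1.0, 1.0])
        r = paired_t(PairedSample(range(4), x, y))
        assert r.n_used == 3 and r.n_excluded == 1

    @settings(deadline=None, max_examples=25)
    @given(shift=st.floats(-50, 50))
    def test_shift_invariance(self, shift):
        x = np.array([1.0, 3.0, 2.0, 5.0])
        y = np.array([0.5, 2.0, 2.5, 3.0])
        a = paired_t(PairedSample(range(4), x, y))
        b = paired_t(PairedSample(range(4), x + shift, y + shift))
        assert a.statistic == pytest.approx(b.statistic, rel=1e-9)


class TestWilcoxonPratt:
    def test_all_zero_differences(self):
        r = wilcoxon_pratt(sample_from_diffs([0.0, 0.0]))
        assert r.p_value == 1.0

    def test_three_positive_differences_exact_quarter(self):
        r = wilcoxon_pratt(sample_from_diffs([1.0, 2.0, 3.0]))
        assert r.method == WILCOXON_PRATT_EXACT
        assert r.p_value == pytest.approx(0.25)

    def test_symmetric_with_zero(self):
        r = wilcoxon_pratt(sample_from_diffs([0.0, 1.0, -1.0]))
        assert r.p_value == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_pratt(PairedSample([], [], []))

    def test_matches_brute_force_enumeration_many_instances(self):
        """Exact path equals an independent 2^m enumeration on random
        instances with zeros and ties (m <= 10)."""
        rng = np.random.default_rng(42)
        for _ in range(60):
            m = int(rng.integers(1, 11))
            diffs = rng.integers(-4, 5, size=m).astype(float)
            p_pkg = wilcoxon_pratt(sample_from_diffs(diffs)).p_value
            p_ref = brute_force_wilcoxon_pratt(diffs)
            assert p_pkg == pytest.approx(p_ref, abs=1e-12), diffs

    def test_approximate_path_matches_scipy_pratt(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0.4, 1.0, 60)
        y = rng.normal(0.0, 1.0, 60)
        r = wilcoxon_pratt(PairedSample(range(60), x, y), exact_cutoff=20)
        assert r.method == WILCOXON_PRATT_APPROX
        ref = sps.wilcoxon(x, y, zero_method="pratt", correction=False, method="approx")
        assert r.p_value == pytest.approx(ref.pvalue, rel=1e-9)


class TestBonferroni:
    @pytest.mark.parametrize("alpha,m,thr,reported", [(0.05, 6, 0.05 / 6, 0.008), (0.05, 1, 0.05, 0.05), (0.05, 5, 0.01, 0.01)])
    def test_threshold_and_reporting(self, alpha, m, thr, reported):
        b = bonferroni(alpha, m)
        assert b.threshold == pytest.approx(thr)
        assert b.reported == pytest.approx(reported)

    def test_zero_comparisons_rejected(self):
        with pytest.raises(ValueError):
            bonferroni(0.05, 0)

    @settings(deadline=None, max_examples=30)
    @given(m=st.integers(1, 50), p=st.floats(0, 1))
    def test_adjusted_significance_implies_raw(self, m, p):
        b = bonferroni(0.05, m)
        if p < b.threshold:
            assert p < 0.05


class TestFrequencyTable:
    def test_single_category_is_100_percent(self):
        t = frequency_table([1, 1, 1], categories=[1])
        assert t["pct"].tolist() == [100.0]

    def test_not_assessed_excluded_from_denominator(self):
        t = frequency_table([0, 0, 1, NOT_ASSESSED], categories=[0, 1])
        assert t.attrs["assessed_n"] == 3
        assert t.attrs["not_assessed_n"] == 1
        assert t["pct"].tolist() == [66.7, 33.3]

    def test_zero_assessed_rejected(self):
        with pytest.raises(ValueError):
            frequency_table([NOT_ASSESSED], categories=[0])

    def test_uncovered_value_rejected(self):
        with pytest.raises(ValueError, match="not covered"):
            frequency_table([0, 9], categories=[0, 1])

    @settings(deadline=None, max_examples=40)
    @given(counts=st.lists(st.integers(0, 60), min_size=1, max_size=5).filter(lambda c: sum(c) > 0))
    def test_percentages_sum_to_100(self, counts):
        t = frequency_table_from_counts({i: c for i, c in enumerate(counts)})
        assert sum(t["pct"]) == pytest.approx(100.0, abs=0.1 * len(counts))


class TestCohort:
    def test_exclusions_applied(self):
        assert included_after_exclusions(78, [16, 1]) == 61

    def test_over_exclusion_rejected(self):
        with pytest.raises(ValueError):
            included_after_exclusions(5, [6])


class TestPairwiseReport:
    def _long(self, conditions_values, n=10):
        rows = []
        for i in range(n):
            for cond, val in conditions_values.items():
                rows.append({"subject": i, "condition": cond, "value": val})
        return pd.DataFrame(rows)

    def test_identical_columns_not_significant(self):
        df = self._long({"A": 1.0, "B": 1.0})
        rep = pairwise_comparison_report(df, [("A", "B")])
        assert rep.p_values.iloc[0, 0] == 1.0
        assert not rep.significant.iloc[0, 0]

    def test_he_zero_vs_special_one_all_52_pairs(self):
        df = self._long({"HE": 0.0, "WAS": 1.0}, n=52)
        rep = pairwise_comparison_report(df, [("HE", "WAS")] * 1)
        assert rep.p_values.iloc[0, 0] < 0.001

    def test_six_comparisons_report_0008_threshold(self):
        df = self._long({c: float(i) for i, c in enumerate("ABCD")})
        comparisons = [("A", "B"), ("A", "C"), ("A", "D"), ("B", "C"), ("B", "D"), ("C", "D")]
        rep = pairwise_comparison_report(df, comparisons)
        assert rep.threshold.reported == pytest.approx(0.008)

    def test_missing_condition_named(self):
        df = self._long({"A": 1.0})
        with pytest.raises(KeyError, match="B"):
            pairwise_comparison_report(df, [("A", "B")])
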