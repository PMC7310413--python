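"""Exact Wilcoxon signed-rank test and paired-cohort summaries."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import rankdata, wilcoxon as scipy_wilcoxon

from ntcpkit import (DegenerateSampleError, PairedSample, RangeError,
                     UndefinedValueError, compare_paired_metric,
                     delta_ntcp_bins, exact_wilcoxon_signed_rank,
                     relative_risk, summarize_volumes)


def enumerate_exact_p(diffs) -> float:
    """Two-sided exact p by brute-force enumeration of all sign
    assignments of the realized rank multiset."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_obs = min(ranks[d > 0].sum(), ranks[d < 0].sum())
    total = ranks.sum()
    count = 0
    for signs in itertools.product((0, 1), repeat=len(ranks)):
        w_pos = sum(r for r, s in zip(ranks, signs) if s)
        if w_pos <= w_obs + 1e-9:
            count += 1
    return min(1.0, 2.0 * count / 2 ** len(ranks))


class TestExactWilcoxon:
    def test_nine_same_signed_pairs(self):
        a = np.arange(1.0, 10.0)
        res = exact_wilcoxon_signed_rank(a, a - 1.0)
        assert res.pvalue == pytest.approx(2 / 512)
        assert round(res.pvalue, 3) == 0.004
        assert res.statistic == 0.0 and res.method == "exact"

    def test_one_discordant_pair_at_rank_one(self):
        a = np.arange(1.0, 10.0)
        b = a - np.array([2, 3, 4, 5, 6, 7, 8, 9, -1.0])
        res = exact_wilcoxon_signed_rank(a, b)
        assert res.pvalue == pytest.approx(4 / 512)
        assert res.pvalue == pytest.approx(enumerate_exact_p(a - b))

    def test_single_pair(self):
        res = exact_wilcoxon_signed_rank([1.0], [0.5])
        assert res.pvalue == 1.0

    def test_all_zero_differences_degenerate(self):
        with pytest.raises(DegenerateSampleError):
            exact_wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])

    def test_zero_differences_dropped_and_counted(self):
        a = np.array([1, 2, 3, 4, 5.0])
        b = np.array([1, 2, 2, 3, 4.0])
        res = exact_wilcoxon_signed_rank(a, b)
        assert res.n_zero_dropped == 2 and res.n_used == 3

    def test_all_same_sign_p_is_two_to_one_minus_n(self):
        for n in range(2, 13):
            a = np.arange(1.0, n + 1)
            res = exact_wilcoxon_signed_rank(a, a - 1.0)
            assert res.pvalue == pytest.approx(2.0 ** (1 - n))

    @settings(deadline=None, max_examples=40)
    @given(seed=st.integers(0, 10_000), n=st.integers(2, 10))
    def test_matches_exhaustive_enumeration(self, seed, n):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=n)
        b = a - rng.normal(0.3, 1.0, size=n)
        if np.all(a == b):
            return
        res = exact_wilcoxon_signed_rank(a, b)
        assert res.pvalue == pytest.approx(enumerate_exact_p(a - b))

    @settings(deadline=None, max_examples=40)
    @given(seed=st.integers(0, 10_000), n=st.integers(3, 9))
    def test_matches_enumeration_with_ties(self, seed, n):
        rng = np.random.default_rng(seed)
        d = rng.integers(-3, 4, size=n).astype(float)
        if np.all(d == 0):
            return
        res = exact_wilcoxon_signed_rank(d, np.zeros(n))
        assert res.pvalue == pytest.approx(enumerate_exact_p(d))

    @settings(deadline=None, max_examples=25)
    @given(seed=st.integers(0, 10_000))
    def test_matches_scipy_on_untied_data(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=12)
        b = a - rng.normal(0.5, 1.0, size=12)
        res = exact_wilcoxon_signed_rank(a, b)
        ref = scipy_wilcoxon(a, b, method="exact")
        assert res.pvalue == pytest.approx(ref.pvalue)
        assert res.statistic == pytest.approx(ref.statistic)

    @settings(deadline=None, max_examples=25)
    @given(seed=st.integers(0, 10_000))
    def test_rank_invariance_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(0.5, 3.0, size=8)
        b = a * rng.uniform(0.5, 1.5, size=8)
        p0 = exact_wilcoxon_signed_rank(a, b).pvalue
        # an increasing affine map preserves both difference signs and the
        # ordering of |differences|, so the exact p must be unchanged
        p1 = exact_wilcoxon_signed_rank(3.0 * a + 1.0, 3.0 * b + 1.0).pvalue
        assert p0 == pytest.approx(p1)

    def test_large_sample_normal_fallback_flagged(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=30)
        b = a - rng.normal(0.5, 1.0, size=30)
        res = exact_wilcoxon_signed_rank(a, b)
        assert res.method == "normal" and "approximation" in res.note


class TestComparisonRow:
    def test_identical_arms_degenerate_row(self):
        sample = PairedSample("A", "B", [1.0, 2.0], [1.0, 2.0])
        row = compare_paired_metric(sample)
        assert np.isnan(row.p_two_sided) and row.significant is None
        assert "zero" in row.note

    def test_constant_shift_significant(self):
        a = np.arange(1.0, 10.0)
        row = compare_paired_metric(PairedSample("A", "B", a, a - 1.0))
        assert round(row.p_two_sided, 3) == 0.004 and row.significant
        assert row.mean_a - row.mean_b == pytest.approx(1.0)

    def test_single_patient(self):
        row = compare_paired_metric(PairedSample("A", "B", [5.0], [4.0]))
        assert row.mean_a == 5.0 and row.mean_b == 4.0
        assert row.p_two_sided == 1.0 and not row.significant

    def test_sample_sd_uses_n_minus_one(self):
        sample = PairedSample("A", "B", [1.0, 2.0, 3.0], [0.0, 0.0, 1.0])
        row = compare_paired_metric(sample)
        assert row.sd_a == pytest.approx(1.0)  # sd([1,2,3], ddof=1) = 1


class TestDeltaBins:
    def test_one_per_bin(self):
        assert delta_ntcp_bins([2.0, 6.0, 12.0]) == (1, 1, 1)

    def test_boundary_five_in_first_bin(self):
        assert delta_ntcp_bins([5.0]) == (1, 0, 0)
        assert delta_ntcp_bins([10.0]) == (0, 1, 0)

    def test_nine_small_deltas(self):
        assert delta_ntcp_bins([0.5] * 9) == (9, 0, 0)

    @settings(deadline=None, max_examples=25)
    @given(seed=st.integers(0, 10_000), n=st.integers(1, 20))
    def test_bins_partition_the_cohort(self, seed, n):
        deltas = np.random.default_rng(seed).normal(4, 6, size=n)
        assert sum(delta_ntcp_bins(deltas)) == n


class TestRelativeRisk:
    def test_halved_risk(self):
        rr, mean, sd = relative_risk(PairedSample("A", "B", [0.20], [0.10]))
        assert rr[0] == pytest.approx(0.5)

    def test_equal_pairs(self):
        rr, mean, sd = relative_risk(
            PairedSample("A", "B", [0.1, 0.2, 0.3], [0.1, 0.2, 0.3]))
        assert mean == pytest.approx(1.0) and sd == pytest.approx(0.0)

    def test_zero_reference_identifies_patient(self):
        with pytest.raises(UndefinedValueError, match="index 1"):
            relative_risk(PairedSample("A", "B", [0.2, 0.0], [0.1, 0.1]))

    def test_uniformly_lower_rival_gives_mean_below_one(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(0.1, 0.3, size=9)
        b = a * rng.uniform(0.2, 0.9, size=9)
        _, mean, _ = relative_risk(PairedSample("A", "B", a, b))
        assert mean < 1.0


class TestSummaries:
    def test_printed_cohort_target_volumes(self):
        gtv = [38.9, 37.6, 51.5, 22.9, 42.6, 31.1, 26.8, 32.7, 54.3]
        ptv = [148.5, 135.5, 178.0, 93.9, 154.1, 126.6, 97.8, 112.9, 168.3]
        assert summarize_volumes(gtv) == (37.6, (22.9, 54.3))
        assert summarize_volumes(ptv) == (135.5, (93.9, 178.0))

    def test_single_value(self):
        assert summarize_volumes([7.0]) == (7.0, (7.0, 7.0))

    def test_empty_rejected(self):
        with pytest.raises(RangeError):
            summarize_volumes([])
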