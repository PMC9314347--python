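import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from circsnp.allelic_imbalance import (
    analyse_allelic,
    descriptive_ci,
    hwe_test,
    normalise_ratio,
    subject_summary,
    wilcoxon_one_sample,
)
from circsnp.data_io import AllelicTriplicate, DataError
from circsnp.datasets import rs4752856_allelic_ratios


def exact_signed_rank_pvalue(values, mu):
    """Enumeration oracle: two-sided exact P over all 2^n sign assignments."""
    d = np.asarray(values, dtype=float) - mu
    d = d[d != 0]
    n = len(d)
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    mean_w = n * (n + 1) / 4
    dev_obs = abs(w_obs - mean_w)
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - mean_w) >= dev_obs - 1e-12:
            count += 1
    return count / 2**n


class TestNormalise:
    @pytest.mark.parametrize(
        "circ,gdna,expected",
        [(0.62, 0.59, 1.05), (1.37, 0.56, 2.45), (0.61, 0.59, 1.03)],
    )
    def test_worked_ratios(self, circ, gdna, expected):
        assert normalise_ratio(circ, gdna) == pytest.approx(expected, abs=0.005)

    def test_identity_and_scale_invariance(self):
        assert normalise_ratio(0.73, 0.73) == 1.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        a=st.floats(min_value=0.01, max_value=10, allow_nan=False),
        b=st.floats(min_value=0.01, max_value=10, allow_nan=False),
        k=st.floats(min_value=0.01, max_value=100, allow_nan=False),
    )
    def test_quotient_scale_invariance(self, a, b, k):
        assert normalise_ratio(a * k, b * k) == pytest.approx(normalise_ratio(a, b), rel=1e-9)

    def test_non_positive_inputs_raise(self):
        with pytest.raises(DataError):
            normalise_ratio(0.0, 0.5)
        with pytest.raises(DataError):
            normalise_ratio(0.5, -1.0)


class TestSubjectSummary:
    def test_published_cohort_median_near_1_25(self):
        summary = subject_summary(rs4752856_allelic_ratios())
        assert summary.n_subjects == 8
        # ratios of the printed 2-dp peak values give 1.26; the published
        # 1.25 came from unrounded peaks
        assert summary.cohort_median == pytest.approx(1.25, abs=0.02)

    def test_constant_replicates(self):
        trips = [AllelicTriplicate("s", "G/A", r, 0.5, 0.5) for r in (1, 2, 3)]
        s = subject_summary(trips)
        assert s.subject_means == {"s": 1.0} and s.cohort_median == 1.0

    def test_homozygous_subjects_are_controls_not_data(self):
        trips = [
            AllelicTriplicate("het", "G/A", 1, 0.7, 0.5),
            AllelicTriplicate("hom", "G/G", 1, 9.0, 0.5),
        ]
        s = subject_summary(trips)
        assert set(s.subject_means) == {"het"}

    def test_exclusion_list_applied_first(self):
        trips = [
            AllelicTriplicate("keep", "G/A", 1, 0.7, 0.5),
            AllelicTriplicate("drop", "G/A", 1, 9.0, 0.5),
        ]
        s = subject_summary(trips, exclusions=["drop"])
        assert set(s.subject_means) == {"keep"}

    def test_means_match_brute_force(self, rng):
        trips = [
            AllelicTriplicate(f"s{i}", "G/A", r, float(rng.uniform(0.3, 2)), float(rng.uniform(0.3, 2)))
            for i in range(10)
            for r in (1, 2, 3)
        ]
        s = subject_summary(trips)
        for i in range(10):
            mine = [t for t in trips if t.subject_id == f"s{i}"]
            expect = sum(t.ag_circ / t.ag_gdna for t in mine) / 3
            assert s.subject_means[f"s{i}"] == pytest.approx(expect)

    def test_all_excluded_raises(self):
        trips = [AllelicTriplicate("s", "G/A", 1, 0.7, 0.5)]
        with pytest.raises(DataError):
            subject_summary(trips, exclusions=["s"])


class TestWilcoxon:
    def test_eight_positive_differences(self):
        # all values above mu: W+ = 36, z = 18/sqrt(51)
        values = [1.17, 1.22, 1.34, 1.30, 1.29, 1.23, 1.21, 2.16]
        r = wilcoxon_one_sample(values, mu=1.0)
        assert r.w_plus == 36.0
        assert r.z == pytest.approx(18 / math.sqrt(51), abs=1e-12)
        assert r.pvalue == pytest.approx(0.0117, abs=2e-4)
        assert r.effect_r == pytest.approx(r.z / math.sqrt(16))

    def test_symmetric_values_give_zero_z(self):
        # dyadic offsets so the absolute differences tie exactly in binary
        r = wilcoxon_one_sample([0.75, 1.25], mu=1.0)
        assert r.z == pytest.approx(0.0) and r.pvalue == pytest.approx(1.0)

    def test_midranks_for_tied_differences(self):
        # |d| = {0.2, 0.1, 0.1}: midranks {3, 1.5, 1.5}; positives 0.2 and one 0.1
        r = wilcoxon_one_sample([0.2, -0.1, 0.1], mu=0.0)
        assert r.w_plus == 4.5

    def test_all_values_at_mu_raise(self):
        with pytest.raises(DataError):
            wilcoxon_one_sample([1.0, 1.0], mu=1.0)

    def test_antisymmetry_under_reflection(self, rng):
        values = rng.uniform(0.5, 2.0, size=12)
        r1 = wilcoxon_one_sample(values, mu=1.0)
        r2 = wilcoxon_one_sample(2.0 - values, mu=1.0)
        assert r2.z == pytest.approx(-r1.z)
        assert r2.pvalue == pytest.approx(r1.pvalue)

    def test_agrees_with_scipy_approx_no_correction(self, rng):
        values = rng.uniform(0.5, 2.0, size=20)
        mine = wilcoxon_one_sample(values, mu=1.0)
        ref = stats.wilcoxon(values - 1.0, correction=False, method="approx")
        assert mine.pvalue == pytest.approx(ref.pvalue, rel=1e-9)

    def test_asymptotic_close_to_exact_enumeration_at_n15(self, rng):
        # the normal approximation should track the exact distribution by n = 15
        for _ in range(3):
            values = rng.normal(1.15, 0.2, size=15)
            mine = wilcoxon_one_sample(values, mu=1.0)
            exact = exact_signed_rank_pvalue(values, 1.0)
            assert mine.pvalue == pytest.approx(exact, abs=0.01)


class TestDescriptiveCi:
    def test_zero_variance(self):
        mean, lo, hi = descriptive_ci([1.0, 1.0, 1.0, 1.0])
        assert (mean, lo, hi) == (1.0, 1.0, 1.0)

    def test_two_point_closed_form(self):
        # t(1, 0.975) = 12.7062; sd = sqrt(2), sem = 1
        mean, lo, hi = descriptive_ci([0.0, 2.0])
        assert mean == 1.0
        assert lo == pytest.approx(1 - 12.7062, abs=1e-3)
        assert hi == pytest.approx(1 + 12.7062, abs=1e-3)

    def test_n_below_two_raises(self):
        with pytest.raises(DataError):
            descriptive_ci([1.0])

    def test_simulation_coverage_near_nominal(self, rng):
        hits = 0
        n_rep = 400
        for _ in range(n_rep):
            sample = rng.normal(0.0, 1.0, size=10)
            _, lo, hi = descriptive_ci(sample)
            hits += lo <= 0.0 <= hi
        assert hits / n_rep == pytest.approx(0.95, abs=0.035)


class TestHwe:
    def test_assayed_cohort_fulfils_hwe(self):
        r = hwe_test(10, 10, 1)
        assert r.minor_allele_freq == pytest.approx(12 / 42)
        assert r.chi2 == pytest.approx(0.5833, abs=1e-3)
        assert r.pvalue_chi2 == pytest.approx(0.445, abs=1e-3)
        assert r.method == "exact" and r.fulfilled

    def test_no_heterozygotes_strongly_rejected(self):
        r = hwe_test(25, 0, 25)
        assert not r.fulfilled and r.pvalue < 1e-6

    def test_exact_proportions_give_zero_chi2(self):
        # 0.8/0.2 alleles at N = 100: 64 / 32 / 4
        r = hwe_test(64, 32, 4)
        assert r.chi2 == pytest.approx(0.0, abs=1e-12)

    def test_exact_matches_full_enumeration(self):
        # independent oracle: enumerate all heterozygote counts directly
        n_major, n_het, n_minor = 6, 4, 2
        n = n_major + n_het + n_minor
        n_min_allele = 2 * n_minor + n_het

        def prob(h):
            rare = (n_min_allele - h) // 2
            common = n - h - rare
            return (
                2**h
                * math.factorial(n)
                / (math.factorial(h) * math.factorial(rare) * math.factorial(common))
            )

        hs = [h for h in range(n_min_allele % 2, n_min_allele + 1, 2)
              if (n_min_allele - h) // 2 + h <= n]
        weights = {h: prob(h) for h in hs}
        total = sum(weights.values())
        p_exact = sum(w for w in weights.values() if w <= weights[n_het]) / total
        assert hwe_test(n_major, n_het, n_minor).pvalue == pytest.approx(p_exact, rel=1e-9)

    def test_large_cohorts_use_chi2(self):
        r = hwe_test(640, 320, 40)
        assert r.method == "chi2" and r.pvalue == r.pvalue_chi2


class TestAnalyseAllelic:
    def test_full_analysis_of_published_cohort(self):
        res = analyse_allelic(rs4752856_allelic_ratios())
        assert res.test.n == 8
        assert res.test.effect_r == pytest.approx(0.63, abs=0.005)
        assert res.test.pvalue == pytest.approx(0.012, abs=0.001)
        assert res.ci_low < res.mean < res.ci_high
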