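"""Frequencies, HWE testing, Yates 2x2 comparison, sample-size formula."""

import math
from fractions import Fraction

import numpy as np
import pytest
from scipy import stats

from pgxpanel import (
    SampleSizeParams,
    allele_and_genotype_frequencies,
    compare_populations,
    hwe_exact_test,
    hwe_test,
    sample_size,
    yates_chi2,
)
from pgxpanel.popgen import NoDataError


def exact_hwe_oracle(n00, n01, n11):
    """Independent exact HWE p-value by direct enumeration with exact
    rational arithmetic (conditional on allele counts)."""
    n = n00 + n01 + n11
    na = n01 + 2 * n11
    rare = min(na, 2 * n - na)
    if rare == 0:
        return 1.0

    def prob(nab):
        naa = (rare - nab) // 2
        nbb = n - nab - naa
        return Fraction(
            math.factorial(n) * 2 ** nab * math.factorial(rare)
            * math.factorial(2 * n - rare),
            math.factorial(naa) * math.factorial(nab) * math.factorial(nbb)
            * math.factorial(2 * n),
        )

    hets = range(rare % 2, rare + 1, 2)
    probs = {h: prob(h) for h in hets}
    p_obs = probs[n01]
    return float(sum(p for p in probs.values() if p <= p_obs))


class TestFrequencies:
    @pytest.mark.parametrize("counts,expected_af", [
        ((25, 50, 25), 0.5),
        ((100, 0, 0), 0.0),
        ((0, 10, 90), 0.95),  # (10 + 180)/200
    ])
    def test_alt_allele_frequency(self, counts, expected_af):
        dosages = [0] * counts[0] + [1] * counts[1] + [2] * counts[2]
        res = allele_and_genotype_frequencies(dosages)
        assert res.alt_af == pytest.approx(expected_af)
        assert sum(res.genotype_fractions) == pytest.approx(1.0)

    def test_missing_excluded_from_denominators(self):
        res = allele_and_genotype_frequencies([0, 1, 2, -1, -1])
        assert res.n_called == 3
        assert res.alt_af == pytest.approx(0.5)

    def test_all_missing_is_no_data(self):
        with pytest.raises(NoDataError):
            allele_and_genotype_frequencies([-1, -1])


class TestHweChiSquare:
    def test_perfect_hwe_proportions_give_zero_statistic(self):
        res = hwe_test((25, 50, 25))
        assert res.chi2 == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)
        assert res.in_hwe

    def test_no_hets_at_half_frequency_gives_chi2_100(self):
        # p = q = 0.5, expected (25, 50, 25): chi2 = 25 + 50 + 25 = 100
        res = hwe_test((50, 0, 50))
        assert res.chi2 == pytest.approx(100.0)
        assert not res.in_hwe

    def test_expected_counts_sum_to_observed_sum(self):
        res = hwe_test((30, 50, 20))
        assert sum(res.expected) == pytest.approx(100.0)

    def test_monomorphic_flagged_not_failed(self):
        res = hwe_test((100, 0, 0))
        assert not res.defined
        assert res.in_hwe is None

    def test_allele_relabeling_invariance(self):
        """Swapping hom-ref and hom-alt leaves the statistic unchanged."""
        rng = np.random.default_rng(2)
        for _ in range(50):
            c = tuple(int(x) for x in rng.integers(0, 40, size=3))
            if c[1] + 2 * c[2] in (0, 2 * sum(c)):
                continue
            a, b = hwe_test(c), hwe_test((c[2], c[1], c[0]))
            assert a.chi2 == pytest.approx(b.chi2)
            assert a.p_value == pytest.approx(b.p_value)

    def test_moderate_table_against_exact_oracle_band(self):
        obs = (30, 50, 20)
        chi_p = hwe_test(obs).p_value
        exact_p = exact_hwe_oracle(*obs)
        # both well inside the acceptance region and of the same order
        assert (chi_p > 0.05) == (exact_p > 0.05)
        assert abs(math.log10(chi_p) - math.log10(exact_p)) < 1.0


class TestHweExact:
    def test_package_exact_test_matches_fraction_oracle(self):
        """The shipped log-factorial exact test agrees with the independent
        exact-rational enumeration across random low-count tables."""
        rng = np.random.default_rng(4)
        for _ in range(200):
            n = int(rng.integers(10, 60))
            q = float(rng.uniform(0.02, 0.4))
            p = 1 - q
            draws = rng.choice(3, size=n, p=[p * p, 2 * p * q, q * q])
            obs = (int((draws == 0).sum()), int((draws == 1).sum()),
                   int((draws == 2).sum()))
            assert hwe_exact_test(obs) == pytest.approx(
                exact_hwe_oracle(*obs), rel=1e-9)


class TestYatesComparison:
    def textbook_yates(self, a, b, c, d):
        """Independently coded textbook formula for the 2x2 table
        [[a, b], [c, d]] (correction clipped at the expected value)."""
        n = a + b + c + d
        chi2 = 0.0
        rows, cols = (a + b, c + d), (a + c, b + d)
        for i, (o1, o2) in enumerate(((a, b), (c, d))):
            for j, o in enumerate((o1, o2)):
                e = rows[i] * cols[j] / n
                chi2 += max(abs(o - e) - 0.5, 0.0) ** 2 / e
        return chi2

    def test_identical_frequencies_not_significant(self):
        res = compare_populations(10, 100, 100, 1000, m=1)
        assert res.chi2_yates == pytest.approx(0.0)
        assert res.p_raw == pytest.approx(1.0)
        assert not res.significant
        assert res.fold_change == pytest.approx(1.0)

    def test_fixed_table_against_formula_and_fisher_direction(self):
        # cohort 30/100 alt vs reference 10/200 alt
        res = compare_populations(30, 100, 10, 200, m=1)
        expected = self.textbook_yates(30, 70, 10, 190)
        assert res.chi2_yates == pytest.approx(expected, rel=1e-12)
        fisher_p = stats.fisher_exact([[30, 70], [10, 190]])[1]
        assert (res.p_raw < 0.05) == (fisher_p < 0.05)

    def test_random_tables_match_independent_formula(self):
        rng = np.random.default_rng(9)
        for _ in range(300):
            a, b, c, d = (int(x) for x in rng.integers(1, 500, size=4))
            got = yates_chi2(np.array([[a, b], [c, d]]))
            assert got == pytest.approx(self.textbook_yates(a, b, c, d), rel=1e-10)

    def test_scipy_continuity_correction_agreement(self):
        """Where the correction is non-degenerate (|obs-exp| >= 0.5 in every
        cell), the statistic equals scipy's Yates-corrected chi-square."""
        rng = np.random.default_rng(13)
        checked = 0
        while checked < 100:
            a, b, c, d = (int(x) for x in rng.integers(5, 400, size=4))
            table = np.array([[a, b], [c, d]], dtype=float)
            exp = np.outer(table.sum(1), table.sum(0)) / table.sum()
            if np.abs(table - exp).min() < 0.5:
                continue
            sp = stats.chi2_contingency(table, correction=True)[0]
            assert yates_chi2(table) == pytest.approx(sp, rel=1e-10)
            checked += 1

    def test_symmetry_under_population_swap(self):
        a = compare_populations(30, 100, 10, 200, m=3)
        b = compare_populations(10, 200, 30, 100, m=3)
        assert a.chi2_yates == pytest.approx(b.chi2_yates)
        assert a.p_raw == pytest.approx(b.p_raw)

    def test_bonferroni_monotone_and_capped(self):
        prev = 0.0
        for m in (1, 2, 5, 50, 5000):
            res = compare_populations(30, 100, 10, 200, m=m)
            assert res.p_bonferroni >= res.p_raw
            assert res.p_bonferroni >= prev
            assert res.p_bonferroni <= 1.0
            prev = res.p_bonferroni

    def test_fold_change_undefined_when_reference_zero(self):
        res = compare_populations(5, 100, 0, 200, m=1)
        assert res.fold_change is None

    def test_zero_marginal_is_no_data(self):
        with pytest.raises(NoDataError):
            compare_populations(0, 0, 10, 100)

    def test_low_expected_cell_warns(self):
        res = compare_populations(1, 2000, 0, 2000, m=1)
        assert res.low_count_warning


class TestSampleSize:
    def test_study_parameters_give_287(self):
        # z=1.96, p=0.16, e=0.03, N=574: n0 = 573.679 -> corrected 286.92 -> 287
        assert sample_size(SampleSizeParams(z=1.96, p=0.16, e=0.03, N=574)) == 287

    def test_infinite_population_limit_is_uncorrected(self):
        n_inf = sample_size(SampleSizeParams(z=1.96, p=0.16, e=0.03, N=None))
        assert n_inf == math.ceil(1.96 ** 2 * 0.16 * 0.84 / 0.03 ** 2)
        big = sample_size(SampleSizeParams(z=1.96, p=0.16, e=0.03, N=10 ** 12))
        assert big == n_inf

    def test_half_maximizes_required_sample(self):
        sizes = {p: sample_size(SampleSizeParams(z=1.96, p=p, e=0.03, N=5000))
                 for p in (0.1, 0.3, 0.5, 0.7, 0.9)}
        assert max(sizes, key=sizes.get) == 0.5

    def test_zero_margin_is_error(self):
        with pytest.raises(ValueError):
            sample_size(SampleSizeParams(e=0.0))
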