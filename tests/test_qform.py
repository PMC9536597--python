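"""Unit and property tests of the chi-square mixture tail machinery."""

import mpmath as mp
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from crossgwas.qform import (
    ChiSquareMixture,
    QFormError,
    combine_pvalues_product_normal,
    fisher_combine,
    mixture_tail,
    product_normal_tail,
)

from conftest import mc_mixture_right_tail, oracle_se


class TestChiSquareMixture:
    def test_zero_coefficients_removed_and_equal_merged(self):
        mix = ChiSquareMixture([1.0, 0.0, 1.0, -0.5], [2, 7, 3, 1])
        assert mix.coeffs == (1.0, -0.5)
        assert mix.dofs == (5, 1)

    def test_invalid_construction(self):
        with pytest.raises(QFormError):
            ChiSquareMixture([], [])
        with pytest.raises(QFormError):
            ChiSquareMixture([0.0], [1])
        with pytest.raises(QFormError):
            ChiSquareMixture([1.0], [0])
        with pytest.raises(QFormError):
            ChiSquareMixture([1.0, 2.0], [1])


class TestMixtureTail:
    def test_chi2_quantile(self):
        # left tail of chi2_1 at its 95% quantile
        res = mixture_tail(ChiSquareMixture([1], [1]), 3.841458820694124, "left")
        assert res.probability == pytest.approx(0.95, abs=1e-10)

    def test_symmetric_mixture_is_half_at_zero(self):
        for a in (0.1, 0.5, 3.0):
            res = mixture_tail(ChiSquareMixture([a, -a], [2, 2]), 0.0, "left")
            assert res.probability == pytest.approx(0.5, abs=1e-10)

    def test_mixed_sign_against_monte_carlo(self):
        mix = ChiSquareMixture([2.0, 1.0, -1.5], [3, 1, 2])
        res = mixture_tail(mix, 1.7, "right")
        rng = np.random.default_rng(20240117)
        mc = mc_mixture_right_tail(mix.coeffs, mix.dofs, 1.7, 10**7, rng)
        assert abs(res.probability - mc) < 3 * oracle_se(res.probability, mc, 10**7)

    def test_all_positive_reduces_to_scaled_chi2(self):
        # equal coefficients with dofs summing to N give a * chi2_N exactly
        for a, dofs, x in [(2.0, (3, 4), 5.0), (0.7, (1, 1, 2), 1.3)]:
            res = mixture_tail(ChiSquareMixture([a] * len(dofs), dofs), x, "left")
            expected = stats.chi2.cdf(x / a, sum(dofs))
            assert res.probability == pytest.approx(expected, abs=1e-10)

    def test_tails_sum_to_one(self):
        mix = ChiSquareMixture([1.2, 0.4, -0.3, -2.0], [1, 2, 1, 1])
        for x in (-5.0, -0.3, 0.0, 1.1, 8.0):
            left = mixture_tail(mix, x, "left").probability
            right = mixture_tail(mix, x, "right").probability
            assert left + right == pytest.approx(1.0, abs=2e-12)

    def test_cdf_nondecreasing(self):
        mix = ChiSquareMixture([0.9, -0.6], [2, 3])
        grid = np.linspace(-15, 15, 41)
        cdf = [mixture_tail(mix, x, "left").probability for x in grid]
        assert np.all(np.diff(cdf) >= -1e-12)

    def test_extreme_tail_methods_agree(self):
        # Ruben-convolution and tilted-contour routes agree with the
        # characteristic-function inversion where all are applicable
        mix = ChiSquareMixture([0.6, 0.3, -0.4, -0.25], [1, 2, 1, 3])
        for x in (4.0, 7.0):
            fast = mixture_tail(mix, x, "right", method="davies").probability
            slow = mixture_tail(mix, x, "right", method="high_precision").probability
            assert slow == pytest.approx(fast, rel=1e-6)

    def test_deep_tail_has_sane_magnitude(self):
        # symmetric +-1/2 mixture at large x: p ~ exp(-x) scale, never 0
        res = mixture_tail(ChiSquareMixture([0.5, -0.5], [1, 1]), 60.0, "right")
        assert res.method in ("ruben", "high_precision")
        assert 0.0 < res.probability < 1e-20

    def test_monte_carlo_method(self):
        mix = ChiSquareMixture([1.0, -1.0], [2, 2])
        res = mixture_tail(mix, 0.0, method="monte_carlo", seed=1)
        assert res.method == "monte_carlo"
        assert res.probability == pytest.approx(0.5, abs=5 * res.achieved_accuracy)

    def test_invalid_accuracy(self):
        with pytest.raises(QFormError):
            mixture_tail(ChiSquareMixture([1], [1]), 1.0, accuracy=0.0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_random_mixture_tail_consistency(self, seed):
        """left+right sum to 1 and probabilities are valid for random mixtures."""
        rng = np.random.default_rng(seed)
        k = rng.integers(1, 6)
        coeffs = rng.uniform(-2, 2, k)
        coeffs[np.abs(coeffs) < 0.05] = 0.3
        dofs = rng.integers(1, 4, k)
        mix = ChiSquareMixture(coeffs, dofs)
        x = float(rng.normal(0, 3))
        left = mixture_tail(mix, x, "left").probability
        right = mixture_tail(mix, x, "right").probability
        assert 0.0 <= left <= 1.0 and 0.0 <= right <= 1.0
        assert left + right == pytest.approx(1.0, abs=1e-9)


class TestProductNormal:
    def test_symmetry_at_zero(self):
        res = product_normal_tail(0.0, 0.0, "right")
        assert res.probability == pytest.approx(0.5, abs=1e-12)

    def test_correlated_against_monte_carlo(self):
        rng = np.random.default_rng(7)
        rho = 0.6
        n = 10**7
        hits = 0
        for _ in range(10):
            z1 = rng.standard_normal(n // 10)
            z2 = rho * z1 + np.sqrt(1 - rho**2) * rng.standard_normal(n // 10)
            hits += int((z1 * z2 > 0.0).sum())
        mc = hits / n
        res = product_normal_tail(0.0, rho, "right")
        assert abs(res.probability - mc) < 3 * oracle_se(res.probability, mc, n)

    def test_rho_zero_matches_bessel_density_integral(self):
        # closed-form pdf of the rho=0 product normal is K0(|x|)/pi
        for x in (0.5, 2.0, 5.0):
            exact = float(mp.quad(lambda t: mp.besselk(0, t), [x, x + 20, mp.inf])
                          / mp.pi)
            got = product_normal_tail(x, 0.0, "right").probability
            assert got == pytest.approx(exact, abs=1e-8)

    def test_invalid_rho(self):
        with pytest.raises(QFormError):
            product_normal_tail(0.0, 1.0)
        with pytest.raises(QFormError):
            product_normal_tail(0.0, -1.2)


class TestCombinators:
    def test_unit_pvalue_gives_half(self):
        # z(1) = 0, so the combined statistic is 0 and its right tail is 0.5
        assert combine_pvalues_product_normal(1.0, 0.5, 1) == pytest.approx(0.5)

    def test_sign_tails_mirror(self):
        p_pos = combine_pvalues_product_normal(0.01, 0.02, 1)
        p_neg = combine_pvalues_product_normal(0.01, 0.02, -1)
        assert p_pos == pytest.approx(p_neg, rel=1e-10)

    def test_beats_fisher_on_diagonal(self):
        # multiplicative combination is stronger than Fisher's for equal,
        # small p-values
        for p in (1e-4, 1e-6, 1e-8):
            assert combine_pvalues_product_normal(p, p, 1) < fisher_combine(p, p)

    def test_divergent_pair_penalized_vs_fisher(self):
        # with one p-value near 1, Fisher's threshold stays finite while the
        # product normal requires far stronger partner evidence
        p_pn = combine_pvalues_product_normal(0.999, 1e-6, 1)
        p_f = fisher_combine(0.999, 1e-6)
        assert p_pn > p_f

    def test_cutoff_partner_order_of_magnitude(self):
        # achieving combined 1e-8 with p1 = 0.05 takes a partner ~1e-16
        p = combine_pvalues_product_normal(0.05, 2.4e-16, 1)
        assert 0.3e-8 < p < 3e-8

    def test_fisher_equals_direct_chi2(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            p1, p2 = rng.uniform(1e-9, 1, 2)
            expected = stats.chi2.sf(-2 * (np.log(p1) + np.log(p2)), 4)
            assert fisher_combine(p1, p2) == pytest.approx(expected, rel=1e-12)

    def test_fisher_bounded_by_partner_evidence(self):
        assert fisher_combine(1.0, 1e-6) == pytest.approx(
            stats.chi2.sf(-2 * np.log(1e-6), 4), rel=1e-12
        )

    def test_domain_errors(self):
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(QFormError):
                combine_pvalues_product_normal(bad, 0.5, 1)
            with pytest.raises(QFormError):
                fisher_combine(0.5, bad)
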