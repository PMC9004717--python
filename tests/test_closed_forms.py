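"""Tests for the closed-form generalized mutual information of the three families."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import ndtr, owens_t

from hcsurrogacy import (
    GaussianPairSpec,
    ProbitGaussianSpec,
    RhoRangeError,
    binary_mi_max,
    binary_mutual_info,
    binary_rho_bounds,
    binary_table_from_margins_rho,
    entropy_power,
    gaussian_mutual_info,
    hc_entropy_discrete,
    hc_entropy_gaussian,
    imath_integral,
    itma_from_mi,
    itma_normalize_discrete_shannon,
    probit_mi_alpha2_owen,
    probit_mi_rho_limit,
    probit_mutual_info,
)
from hcsurrogacy.closed_forms import ProbabilityTable2x2, imath_integral_gh

INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)
ALPHAS = (0.5, 1.0, 2.0)


def random_table(rng) -> ProbabilityTable2x2:
    cells = rng.dirichlet(np.ones(4))
    return ProbabilityTable2x2(*cells)


# ---------------------------------------------------------------------------
# Gaussian family


class TestGaussianMI:
    @pytest.mark.parametrize("alpha", ALPHAS)
    def test_independence_gives_zero(self, alpha):
        res = gaussian_mutual_info(GaussianPairSpec(sigma_t=0.7, sigma_s=2.0, rho=0.0), alpha)
        assert res.mi == 0.0 and res.itma == 0.0

    def test_shannon_value(self):
        res = gaussian_mutual_info(GaussianPairSpec(rho=0.8), 1.0)
        assert res.mi == pytest.approx(-0.5 * math.log(0.36), abs=1e-12)

    def test_order_two_frozen_oracle_value(self):
        # frozen Monte-Carlo plug-in value (4e6 samples): 0.1250 +/- 0.0001
        spec = GaussianPairSpec(sigma_t=INV_SQRT_2PI, sigma_s=INV_SQRT_2PI, rho=0.6)
        assert gaussian_mutual_info(spec, 2.0).mi == pytest.approx(0.125, abs=3e-4)

    @pytest.mark.parametrize("alpha", ALPHAS)
    def test_monotone_in_absolute_correlation(self, alpha):
        rhos = np.linspace(0.0, 0.99, 12)
        vals = [gaussian_mutual_info(GaussianPairSpec(rho=r), alpha).mi for r in rhos]
        assert all(a < b for a, b in zip(vals, vals[1:]))
        neg = [gaussian_mutual_info(GaussianPairSpec(rho=-r), alpha).mi for r in rhos]
        np.testing.assert_allclose(vals, neg, rtol=1e-12)

    def test_scale_dependence_except_at_shannon(self):
        small = GaussianPairSpec(sigma_t=0.5, sigma_s=0.5, rho=0.6)
        large = GaussianPairSpec(sigma_t=2.0, sigma_s=2.0, rho=0.6)
        for alpha in (0.5, 2.0):
            assert gaussian_mutual_info(small, alpha).mi != pytest.approx(
                gaussian_mutual_info(large, alpha).mi, rel=1e-6
            )
        assert gaussian_mutual_info(small, 1.0).mi == pytest.approx(
            gaussian_mutual_info(large, 1.0).mi, abs=1e-14
        )

    def test_symmetry_under_swap(self, rng):
        for _ in range(20):
            st_, ss, r = rng.uniform(0.2, 3.0), rng.uniform(0.2, 3.0), rng.uniform(-0.95, 0.95)
            for alpha in ALPHAS:
                a = gaussian_mutual_info(GaussianPairSpec(sigma_t=st_, sigma_s=ss, rho=r), alpha)
                b = gaussian_mutual_info(GaussianPairSpec(sigma_t=ss, sigma_s=st_, rho=r), alpha)
                assert a.mi == pytest.approx(b.mi, rel=1e-12)

    def test_perfect_correlation_limits(self):
        assert gaussian_mutual_info(GaussianPairSpec(rho=1.0), 2.0).mi == math.inf
        assert gaussian_mutual_info(GaussianPairSpec(rho=1.0), 1.0).mi == math.inf
        res = gaussian_mutual_info(GaussianPairSpec(rho=1.0), 0.5)
        sup = (2 * math.pi) ** 0.5 / (0.5 * 0.5)
        assert res.mi == pytest.approx(sup)
        assert res.itma_normalized == pytest.approx(1.0)

    def test_alpha_below_one_normalization(self):
        # when the prefactor supremum is 1 the normalization is itma / (1 - e^-2)
        spec = GaussianPairSpec(sigma_t=INV_SQRT_2PI, sigma_s=INV_SQRT_2PI * 0.25, rho=0.7)
        alpha = 0.5
        sup = (2 * math.pi * spec.sigma_t * spec.sigma_s) ** 0.5 / 0.25
        res = gaussian_mutual_info(spec, alpha)
        assert res.normalization_kind == "alpha_lt1_sup"
        assert 0.0 <= res.itma <= res.itma_normalized <= 1.0
        expected = res.itma / (1.0 - math.exp(-2.0 * sup))
        assert res.itma_normalized == pytest.approx(expected, rel=1e-12)

    def test_alpha_continuity_at_one(self):
        spec = GaussianPairSpec(sigma_t=1.3, sigma_s=0.6, rho=0.55)
        ref = gaussian_mutual_info(spec, 1.0).mi
        for alpha in (1.0 - 1e-4, 1.0 + 1e-4):
            assert gaussian_mutual_info(spec, alpha).mi == pytest.approx(ref, abs=1e-4)

    def test_entropy_power_ratio_differs_from_itma_for_alpha_two(self):
        # the entropy-power uncertainty-reduction ratio and 1 - e^{-2 I} agree
        # at the Shannon order only; at order 2 they must differ
        spec = GaussianPairSpec(sigma_t=1.0, sigma_s=1.0, rho=0.8)
        alpha = 2.0
        h_t = hc_entropy_gaussian(spec.sigma_t, alpha)
        h_t_given_s = hc_entropy_gaussian(spec.sigma_t * math.sqrt(1 - spec.rho**2), alpha)
        ratio = (entropy_power(h_t) - entropy_power(h_t_given_s)) / entropy_power(h_t)
        itma = gaussian_mutual_info(spec, alpha).itma
        assert abs(ratio - itma) > 1e-3


# ---------------------------------------------------------------------------
# binary family


class TestBinaryMI:
    @pytest.mark.parametrize("alpha", ALPHAS)
    def test_product_table_gives_zero(self, alpha, rng):
        for _ in range(10):
            pt, ps = rng.uniform(0.05, 0.95, 2)
            table = ProbabilityTable2x2(
                (1 - pt) * (1 - ps), pt * (1 - ps), (1 - pt) * ps, pt * ps
            )
            assert binary_mutual_info(table, alpha).mi == pytest.approx(0.0, abs=1e-12)

    def test_perfect_dependence_values(self):
        table = ProbabilityTable2x2(0.5, 0.0, 0.0, 0.5)
        assert binary_mutual_info(table, 2.0).mi == pytest.approx(0.25, abs=1e-14)
        assert binary_mutual_info(table, 1.0).mi == pytest.approx(math.log(2.0), abs=1e-14)

    @settings(max_examples=60, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_symmetric_in_endpoints(self, seed):
        table = random_table(np.random.default_rng(seed))
        for alpha in ALPHAS:
            assert binary_mutual_info(table, alpha).mi == pytest.approx(
                binary_mutual_info(table.transpose(), alpha).mi, abs=1e-12
            )

    def test_order_two_mi_bounded_by_min_marginal_entropy(self, rng):
        """For orders above 1 the MI never exceeds the smaller marginal entropy."""
        for _ in range(1000):
            table = random_table(rng)
            h_t2 = hc_entropy_discrete(table.margin_t, 2.0)
            h_s2 = hc_entropy_discrete(table.margin_s, 2.0)
            assert binary_mutual_info(table, 2.0).mi <= min(h_t2, h_s2) + 1e-12

    def test_order_half_has_no_marginal_entropy_lower_bound(self):
        """A claimed a<1 lower bound I >= max(HC(T), HC(S)) is refuted.

        Independence is an immediate counterexample (I = 0 with positive
        marginal entropies), and the bound fails even for strongly
        positively correlated tables, as below.  Both evaluation routes
        (the double-sum form and the entropy decomposition) agree on the
        counterexample value.
        """
        ind = binary_table_from_margins_rho(0.4, 0.6, 0.0)
        assert binary_mutual_info(ind, 0.5).mi == pytest.approx(0.0, abs=1e-12)
        assert hc_entropy_discrete(ind.margin_t, 0.5) > 0.5

        table = ProbabilityTable2x2(0.575, 0.131, 0.002, 0.292)
        assert table.rho > 0.7  # strongly concordant
        mi = binary_mutual_info(table, 0.5).mi
        h_t = hc_entropy_discrete(table.margin_t, 0.5)
        h_s = hc_entropy_discrete(table.margin_s, 0.5)
        decomposition = (
            h_t + h_s + 0.5 * h_t * h_s - hc_entropy_discrete(table.cells(), 0.5)
        )
        assert mi == pytest.approx(decomposition, abs=1e-12)
        assert mi < max(h_t, h_s) - 0.2

    def test_monotone_in_rho_under_concordance_condition(self):
        """d I/d rho has the sign of (p10^(a-1)+p01^(a-1)-p00^(a-1)-p11^(a-1)) * a/(1-a)."""
        pt, ps = 0.6, 0.55
        lo, hi = binary_rho_bounds(pt, ps)
        rhos = np.linspace(0.05, hi - 1e-6, 10)
        for alpha in (0.5, 2.0):
            vals = []
            for r in rhos:
                table = binary_table_from_margins_rho(pt, ps, r)
                c = table.cells() ** (alpha - 1.0)
                condition = c[0] + c[3] - c[1] - c[2]  # p00, p11 vs p10, p01
                # proof's direction: increasing iff condition > 0 for a > 1,
                # and iff condition < 0 for a < 1
                expected_increasing = condition > 0 if alpha > 1 else condition < 0
                assert expected_increasing  # holds throughout this concordant grid
                vals.append(binary_mutual_info(table, alpha).mi)
            assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_alpha_continuity_at_one(self, rng):
        table = random_table(rng)
        ref = binary_mutual_info(table, 1.0).mi
        for alpha in (1.0 - 1e-4, 1.0 + 1e-4):
            assert binary_mutual_info(table, alpha).mi == pytest.approx(ref, abs=1e-4)

    def test_discordant_table_can_go_negative_above_order_one(self):
        # unlike Shannon MI, the order-2 value is negative for this strongly
        # discordant table: (sum margins^2)^2 - sum cells^2 changes sign
        table = ProbabilityTable2x2(0.5, 0.25, 0.25, 0.0)
        res = binary_mutual_info(table, 2.0)
        assert res.mi == pytest.approx(-0.015625, abs=1e-12)
        assert res.itma < 0 and res.itma_normalized is None
        # Shannon MI of the same table is, as always, nonnegative
        assert binary_mutual_info(table, 1.0).mi > 0


class TestMarginsRhoRoundTrip:
    def test_independence_cells(self):
        table = binary_table_from_margins_rho(0.5, 0.5, 0.0)
        np.testing.assert_allclose(table.cells(), 0.25)

    def test_perfect_positive_correlation(self):
        table = binary_table_from_margins_rho(0.5, 0.5, 1.0)
        np.testing.assert_allclose(table.cells(), [0.5, 0.0, 0.0, 0.5], atol=1e-15)

    def test_infeasible_rho_reports_interval(self):
        with pytest.raises(RhoRangeError, match="admissible interval"):
            binary_table_from_margins_rho(0.7, 0.3, 0.9)

    def test_round_trip_over_feasible_grid(self, rng):
        for _ in range(200):
            pt, ps = rng.uniform(0.05, 0.95, 2)
            lo, hi = binary_rho_bounds(pt, ps)
            rho = rng.uniform(lo + 1e-9, hi - 1e-9)
            table = binary_table_from_margins_rho(pt, ps, rho)
            assert table.rho == pytest.approx(rho, abs=1e-9)
            np.testing.assert_allclose(table.margin_t[1], pt, atol=1e-12)
            np.testing.assert_allclose(table.margin_s[1], ps, atol=1e-12)

    def test_bounds_match_brute_force_feasibility(self, rng):
        """The analytic interval agrees with a cell-nonnegativity scan."""
        for _ in range(20):
            pt, ps = rng.uniform(0.1, 0.9, 2)
            lo, hi = binary_rho_bounds(pt, ps)
            d = math.sqrt(pt * (1 - pt) * ps * (1 - ps))
            for rho in np.linspace(-1, 1, 401):
                shift = rho * d
                cells = np.array(
                    [
                        (1 - pt) * (1 - ps) + shift,
                        pt * (1 - ps) - shift,
                        (1 - pt) * ps - shift,
                        pt * ps + shift,
                    ]
                )
                feasible = (cells >= -1e-12).all()
                assert feasible == (lo - 1e-9 <= rho <= hi + 1e-9)


class TestBinaryMIMax:
    def test_symmetric_fair_margins(self):
        assert binary_mi_max(0.5, 0.5, 2.0) == pytest.approx(0.25, abs=1e-14)
        assert binary_mi_max(0.5, 0.5, 1.0) == pytest.approx(math.log(2.0), abs=1e-14)

    @pytest.mark.parametrize("alpha", ALPHAS)
    def test_dominates_mi_over_rho_grid(self, alpha, rng):
        for _ in range(25):
            pt, ps = rng.uniform(0.1, 0.9, 2)
            cap = binary_mi_max(pt, ps, alpha)
            lo, hi = binary_rho_bounds(pt, ps)
            for rho in np.linspace(lo + 1e-9, hi - 1e-9, 21):
                table = binary_table_from_margins_rho(pt, ps, rho)
                assert binary_mutual_info(table, alpha).mi <= cap + 1e-10

    def test_max_attained_at_boundary_by_grid_search(self):
        lo, hi = binary_rho_bounds(0.5, 0.5)
        grid = [
            binary_mutual_info(binary_table_from_margins_rho(0.5, 0.5, r), 2.0).mi
            for r in np.linspace(lo, hi, 101)
        ]
        assert max(grid) == pytest.approx(binary_mi_max(0.5, 0.5, 2.0), abs=1e-10)

    def test_normalized_itma_at_most_one(self, rng):
        for _ in range(50):
            table = random_table(rng)
            for alpha in ALPHAS:
                res = binary_mutual_info(table, alpha)
                if res.mi < 0:
                    assert res.itma_normalized is None  # no cap for negative values
                    continue
                assert res.itma_normalized is not None
                assert res.itma - 1e-12 <= res.itma_normalized <= 1.0 + 1e-9


# ---------------------------------------------------------------------------
# probit family


class TestImathIntegral:
    def test_zero_slope_is_power_of_cdf(self):
        for a, alpha in [(0.3, 2.0), (-1.2, 0.5), (0.0, 2.0)]:
            assert imath_integral(a, 0.0, alpha) == pytest.approx(
                float(ndtr(a)) ** alpha, abs=1e-14
            )
        assert imath_integral(0.0, 0.0, 2.0) == pytest.approx(0.25)

    def test_order_two_owen_identity(self):
        # imath^(2)(a,b) = Phi(a/sqrt(1+b^2)) - 2 T(a/sqrt(1+b^2), 1/sqrt(1+2b^2))
        for a, b in [(1.0, 1.0), (-0.5, 2.0), (0.7, -1.3), (2.0, 0.4)]:
            h = a / math.sqrt(1 + b * b)
            expected = float(ndtr(h)) - 2.0 * float(owens_t(h, 1.0 / math.sqrt(1 + 2 * b * b)))
            assert imath_integral(a, b, 2.0) == pytest.approx(expected, abs=1e-8)
        assert imath_integral(1.0, 1.0, 2.0) == pytest.approx(0.634, abs=5e-4)

    @pytest.mark.parametrize("alpha", [0.5, 1.0, 2.0, 3.5])
    def test_adaptive_quadrature_cross_checked_by_gauss_hermite(self, alpha):
        # independent evaluation routes agree at moderate slopes, where the
        # Hermite rule is itself accurate
        for a, b in [(-1.5, 0.7), (0.0, 1.5), (1.2, -0.4), (0.3, 1.0)]:
            assert imath_integral(a, b, alpha) == pytest.approx(
                imath_integral_gh(a, b, alpha, nodes=256), abs=1e-10
            )


class TestProbitMI:
    @pytest.mark.parametrize("alpha", ALPHAS)
    @pytest.mark.parametrize("p1", [0.2, 0.5, 0.8])
    def test_independence_gives_zero(self, alpha, p1):
        res = probit_mutual_info(ProbitGaussianSpec(p1=p1, sigma_s=0.7, rho=0.0), alpha)
        assert res.mi == pytest.approx(0.0, abs=1e-12)

    def test_alpha_continuity_at_one(self):
        spec = ProbitGaussianSpec(p1=0.5, sigma_s=1.0, rho=0.5)
        ref = probit_mutual_info(spec, 1.0).mi
        for alpha in (1.0 - 1e-4, 1.0 + 1e-4):
            assert probit_mutual_info(spec, alpha).mi == pytest.approx(ref, abs=1e-4)

    def test_boundary_rho_directs_to_limit(self):
        with pytest.raises(ValueError, match="probit_mi_rho_limit"):
            probit_mutual_info(ProbitGaussianSpec(p1=0.4, rho=1.0), 2.0)

    def test_monotone_in_absolute_rho(self):
        for alpha in ALPHAS:
            vals = [
                probit_mutual_info(ProbitGaussianSpec(p1=0.35, rho=r), alpha).mi
                for r in np.linspace(0.0, 0.95, 10)
            ]
            assert all(a < b for a, b in zip(vals, vals[1:]))


class TestProbitRhoLimit:
    def test_symmetric_fair_case_value(self):
        # p1 = 0.5, sigma_S^2 = 1/(2 pi), alpha = 2: (-1/sqrt2)(0.5 - 1) = 1/(2 sqrt2)
        spec = ProbitGaussianSpec(p1=0.5, sigma_s=INV_SQRT_2PI, rho=1.0)
        assert probit_mi_rho_limit(spec, 2.0) == pytest.approx(1.0 / (2.0 * math.sqrt(2.0)))

    def test_continuity_with_interior_values(self):
        for p1 in (0.3, 0.5, 0.7):
            spec_limit = ProbitGaussianSpec(p1=p1, sigma_s=1.0, rho=1.0)
            limit = probit_mi_rho_limit(spec_limit, 2.0)
            near = probit_mutual_info(
                ProbitGaussianSpec(p1=p1, sigma_s=1.0, rho=1.0 - 1e-6), 2.0
            ).mi
            assert near == pytest.approx(limit, abs=1e-3)

    def test_symmetric_in_rho_sign_and_shannon_unsupported(self):
        pos = probit_mi_rho_limit(ProbitGaussianSpec(p1=0.3, rho=1.0), 2.0)
        neg = probit_mi_rho_limit(ProbitGaussianSpec(p1=0.3, rho=-1.0), 2.0)
        assert pos == pytest.approx(neg, abs=1e-14)
        with pytest.raises(ValueError):
            probit_mi_rho_limit(ProbitGaussianSpec(p1=0.3, rho=1.0), 1.0)


class TestProbitOwenForm:
    def test_zero_rho_agrees_with_independence(self):
        assert probit_mi_alpha2_owen(ProbitGaussianSpec(p1=0.3, rho=0.0)) == pytest.approx(
            0.0, abs=1e-14
        )

    def test_matches_general_quadrature_on_grid(self):
        for p1 in (0.1, 0.3, 0.5, 0.7, 0.9):
            for rho in (-0.9, -0.5, 0.0, 0.3, 0.7, 0.95):
                for sigma in (0.5, 1.0):
                    spec = ProbitGaussianSpec(p1=p1, sigma_s=sigma, rho=rho)
                    assert probit_mi_alpha2_owen(spec) == pytest.approx(
                        probit_mutual_info(spec, 2.0).mi, abs=1e-8
                    )


# ---------------------------------------------------------------------------
# ITMA transforms


class TestItmaTransforms:
    def test_reference_points(self):
        assert itma_from_mi(0.0) == 0.0
        assert itma_from_mi(0.5) == pytest.approx(1.0 - math.exp(-1.0))
        assert itma_from_mi(math.inf) == 1.0

    def test_negative_mi_rejected_but_roundoff_tolerated(self):
        assert itma_from_mi(-1e-13) == 0.0
        with pytest.raises(ValueError):
            itma_from_mi(-1e-6)

    def test_discrete_shannon_normalization(self):
        h = math.log(2.0)
        # fair-coin endpoint with perfect dependence saturates the cap
        r2 = binary_mutual_info(ProbabilityTable2x2(0.5, 0.0, 0.0, 0.5), 1.0).itma
        assert itma_normalize_discrete_shannon(r2, h) == pytest.approx(1.0, abs=1e-12)
        assert itma_normalize_discrete_shannon(0.0, h) == 0.0
        with pytest.raises(ValueError):
            itma_normalize_discrete_shannon(0.5, 0.0)
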