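import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from coopeq import (
    DEFAULT_PAYOFFS,
    EquilibriumPoint,
    MarkovStrategy,
    StationaryProfile,
    best_response_check,
    curve_alpha_given_gamma,
    deviation_report,
    equilibrium_residual,
    expected_payoff,
    foc_residual,
    max_tolerance_point,
    stationary_cooperation,
    stationary_joint,
    transition_matrix,
)
from coopeq.markov import DegenerateChainError

interior = st.floats(0.02, 0.98)


class TestStationaryCooperation:
    def test_unconditional_mixing(self):
        s = MarkovStrategy(0.4, 0.4)
        prof = stationary_cooperation(s, s)
        assert prof.p1c == pytest.approx(0.4) and prof.p2c == pytest.approx(0.4)

    def test_symmetric_point(self):
        s = MarkovStrategy(0.3, 0.8)
        prof = stationary_cooperation(s, s)
        assert prof.p1c == pytest.approx(0.6, abs=1e-12)

    @given(interior, interior, interior, interior)
    def test_solves_the_linear_fixed_point(self, a1, g1, a2, g2):
        """The closed form satisfies p_i = gamma_i p_j + alpha_i (1 - p_j)."""
        s1, s2 = MarkovStrategy(a1, g1), MarkovStrategy(a2, g2)
        prof = stationary_cooperation(s1, s2)
        assert prof.p1c == pytest.approx(
            g1 * prof.p2c + a1 * (1 - prof.p2c), abs=1e-12
        )
        assert prof.p2c == pytest.approx(
            g2 * prof.p1c + a2 * (1 - prof.p1c), abs=1e-12
        )

    def test_tit_for_tat_pair_is_degenerate(self):
        tft = MarkovStrategy(0.0, 1.0)
        with pytest.raises(DegenerateChainError, match="initial|not unique"):
            stationary_cooperation(tft, tft)


class TestTransitionMatrix:
    def test_always_cooperate_absorbs_immediately(self):
        s = MarkovStrategy(1.0, 1.0)
        T = transition_matrix(s, s)
        assert T[:, 0] == pytest.approx(np.ones(4))

    def test_rows_stochastic(self):
        T = transition_matrix(MarkovStrategy(0.2, 0.7), MarkovStrategy(0.5, 0.9))
        assert T.sum(axis=1) == pytest.approx(np.ones(4))
        assert (T >= 0).all()

    def test_tit_for_tat_cycle_has_no_unique_stationary_law(self):
        tft = MarkovStrategy(0.0, 1.0)
        with pytest.raises(DegenerateChainError):
            stationary_joint(tft, tft)

    @given(interior, interior, interior, interior)
    def test_joint_law_is_product_of_marginals(self, a1, g1, a2, g2):
        """Eigenvector oracle: the 4-state stationary law equals the outer
        product of the closed-form marginals (zero stationary covariance)."""
        s1, s2 = MarkovStrategy(a1, g1), MarkovStrategy(a2, g2)
        pi = stationary_joint(s1, s2)
        prof = stationary_cooperation(s1, s2)
        p1, p2 = prof.p1c, prof.p2c
        outer = np.array(
            [p1 * p2, p1 * (1 - p2), (1 - p1) * p2, (1 - p1) * (1 - p2)]
        )
        assert pi == pytest.approx(outer, abs=1e-10)


class TestExpectedPayoff:
    @pytest.mark.parametrize(
        "p1, p2, expected", [(1, 1, 5), (0, 0, 1), (0, 1, 10), (1, 0, 0)]
    )
    def test_corners_are_the_prizes(self, p1, p2, expected):
        assert expected_payoff(StationaryProfile(p1, p2)) == expected

    @given(interior, interior)
    def test_default_prizes_reduce_to_printed_coefficients(self, p1, p2):
        u = expected_payoff(StationaryProfile(p1, p2))
        assert u == pytest.approx(-4 * p1 * p2 - p1 + 9 * p2 + 1, abs=1e-12)


class TestEquilibriumCurve:
    def test_tit_for_tat_is_on_the_conic(self):
        assert equilibrium_residual(0.0, 1.0) == pytest.approx(0.0, abs=1e-12)

    def test_mutual_defection_is_not(self):
        assert equilibrium_residual(0.0, 0.0) == pytest.approx(1.0)

    @given(interior, interior)
    def test_conic_matches_printed_quadratic(self, a, g):
        expected = 5 * a**2 + 9 * g**2 - 14 * a * g + 14 * a - 10 * g + 1
        assert equilibrium_residual(a, g) == pytest.approx(expected, abs=1e-9)

    def test_curve_alpha_at_full_reciprocity(self):
        assert curve_alpha_given_gamma(1.0) == pytest.approx(0.0, abs=1e-12)

    def test_curve_alpha_known_values(self):
        assert curve_alpha_given_gamma(7 / 31) == pytest.approx(0.071382, abs=5e-7)
        # below gamma = 1/9 the larger root goes formally negative
        assert curve_alpha_given_gamma(2 / 19) == pytest.approx(-0.003765, abs=5e-7)

    @given(st.floats(0.01, 0.99))
    def test_curve_points_have_zero_residual(self, g):
        a = curve_alpha_given_gamma(g)
        assert equilibrium_residual(a, g) == pytest.approx(0.0, abs=1e-9)


class TestMaxTolerancePoint:
    def test_closed_form(self):
        pt = max_tolerance_point()
        assert pt.alpha == pytest.approx(7 - math.sqrt(45), abs=1e-14)
        assert pt.gamma == pytest.approx((5 + 7 * pt.alpha) / 9, abs=1e-14)
        assert equilibrium_residual(pt.alpha, pt.gamma) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_rounds_to_point_three_point_eight(self):
        pt = max_tolerance_point()
        assert round(pt.alpha, 1) == 0.3
        assert round(pt.gamma, 1) == 0.8

    def test_is_the_maximum_over_the_curve(self):
        pt = max_tolerance_point()
        gammas = np.linspace(0.01, 0.999, 2000)
        alphas = [curve_alpha_given_gamma(g) for g in gammas]
        assert max(alphas) <= pt.alpha + 1e-6


class TestFirstOrderCondition:
    def test_zero_on_the_curve(self):
        for g in np.linspace(0.2, 0.99, 25):
            a = curve_alpha_given_gamma(g)
            if not 0 <= a < g:
                continue
            assert foc_residual(MarkovStrategy(a, g)) == pytest.approx(0.0, abs=1e-8)

    def test_zero_sets_coincide(self):
        """Points with zero first-order condition lie on the conic and
        vice versa (away from the gamma = alpha diagonal)."""
        for g in np.linspace(0.3, 0.95, 14):
            for a in np.linspace(0.01, g - 0.05, 10):
                s = MarkovStrategy(a, g)
                p = a / (1 + a - g)
                conic = equilibrium_residual(a, g)
                foc = foc_residual(s)
                # the conic is foc times -(1 + a - g)
                assert conic == pytest.approx(-(1 + a - g) * foc, abs=1e-9)

    def test_near_diagonal_is_far_from_curve(self):
        assert abs(foc_residual(MarkovStrategy(0.5, 0.5001))) > 1.0

    def test_diagonal_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            foc_residual(MarkovStrategy(0.4, 0.4))

    def test_printed_default_form(self):
        a, g = 0.1, 0.7
        p = a / (1 + a - g)
        assert foc_residual(MarkovStrategy(a, g)) == pytest.approx(
            -8 * (g - a) * p + 9 * (g - a) - 4 * a - 1, abs=1e-12
        )


class TestBestResponse:
    def test_no_profitable_deviation_on_sampled_curve_points(self):
        gammas = np.linspace(0.35, 0.99, 20)
        for g in gammas:
            a = curve_alpha_given_gamma(g)
            assert 0 <= a < g
            gain = best_response_check(EquilibriumPoint(a, g), grid_step=0.01)
            assert gain <= 1e-9

    def test_max_tolerance_point_is_an_equilibrium(self):
        assert best_response_check(max_tolerance_point(), 0.01) <= 1e-9

    def test_off_curve_point_is_improvable(self):
        assert best_response_check(EquilibriumPoint(0.5, 0.9), 0.02) > 0.01


class TestDeviationReport:
    def test_on_curve_point_has_zero_distance_and_loss(self):
        g = 0.8
        a = curve_alpha_given_gamma(g)
        rep = deviation_report(a, g)
        assert rep.distance == pytest.approx(0.0, abs=1e-12)
        assert rep.deviation_pct == pytest.approx(0.0, abs=1e-9)

    def test_published_distance_lowest_cooperation_session(self):
        rep = deviation_report(23 / 221, 7 / 31)
        assert rep.distance == pytest.approx(0.03269024, abs=5e-9)

    def test_published_payoff_loss(self):
        rep = deviation_report(21 / 92, 4 / 28)
        assert rep.deviation_pct == pytest.approx(1.68, abs=5e-3)

    def test_formal_extension_flagged_below_gamma_one_ninth(self):
        rep = deviation_report(14 / 101, 2 / 19)
        assert rep.formal_extension
        assert rep.alpha_curve < 0

    def test_loss_nonnegative_off_curve(self):
        for a_exp in (0.05, 0.2, 0.5, 0.9):
            rep = deviation_report(a_exp, 0.8)
            assert rep.deviation_pct >= -1e-12
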