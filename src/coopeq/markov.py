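"""Iterated Prisoner's Dilemma in memory-one (Markov) strategies.

A strategy is a pair (α, γ): the probability of cooperating after the
partner defected (tolerance to defection) and after the partner
cooperated (reciprocal cooperation).  A pair of such strategies induces
a Markov chain over the joint move states {CC, CD, DC, DD}; for
interior strategies its stationary law is the product of the per-player
stationary cooperation probabilities

    p_i = (α_i - α_j (α_i - γ_i)) / (1 - (α_1 - γ_1)(α_2 - γ_2)),

and player 1's long-run payoff is the bilinear form of the stage
payoffs in (p_1, p_2); with prizes (10, 5, 1, 0) it reads
U1 = -4 p_1 p_2 - p_1 + 9 p_2 + 1.

The symmetric totally mixed Nash equilibria (α, α, γ, γ) form the conic

    5α² + 9γ² - 14αγ + 14α - 10γ + 1 = 0,

whose unit-square branch runs from tit-for-tat (0, 1) through the
point of maximum tolerance (α*, γ*) = (7 - 3√5, (5 + 7α*)/9) ≈
(0.292, 0.783).  This module evaluates the stationary model, the
equilibrium curve and first-order condition, and the per-session
deviation report (signed tolerance distance to the curve and percent
payoff loss of the deviating player) used by the empirical pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .games_core import DEFAULT_PAYOFFS, PDPayoffs

__all__ = [
    "MarkovStrategy",
    "StationaryProfile",
    "EquilibriumPoint",
    "DeviationReport",
    "DegenerateChainError",
    "stationary_cooperation",
    "transition_matrix",
    "stationary_joint",
    "expected_payoff",
    "equilibrium_residual",
    "curve_alpha_given_gamma",
    "max_tolerance_point",
    "foc_residual",
    "best_response_check",
    "deviation_report",
]

#: Order of the joint previous-round states used by ``transition_matrix``.
STATE_ORDER = ("CC", "CD", "DC", "DD")


class DegenerateChainError(ValueError):
    """The joint chain has no unique stationary law (e.g. a pair of exact
    tit-for-tat strategies): the long-run play depends on the initial
    conditions and must be pinned down by a first-round convention."""


@dataclass(frozen=True)
class MarkovStrategy:
    """Memory-one strategy (α = tolerance to defection, γ = reciprocal
    cooperation).

    Behavioral strategies live in the unit square; the stationary-model
    formulas below are also formally evaluated outside it where the
    equilibrium curve requires it (see ``curve_alpha_given_gamma``).
    ``in_unit_square`` distinguishes the two regimes; the simulator and
    transition matrix require it to be True.
    """

    alpha: float
    gamma: float

    @property
    def in_unit_square(self) -> bool:
        return 0.0 <= self.alpha <= 1.0 and 0.0 <= self.gamma <= 1.0


@dataclass(frozen=True)
class StationaryProfile:
    """Stationary cooperation probabilities of the two players."""

    p1c: float
    p2c: float


@dataclass(frozen=True)
class EquilibriumPoint:
    """A point (α, γ) on the symmetric totally mixed equilibrium conic."""

    alpha: float
    gamma: float


def stationary_cooperation(
    s1: MarkovStrategy, s2: MarkovStrategy
) -> StationaryProfile:
    """Unique stationary cooperation probabilities of a strategy pair.

    Solves the linear fixed point p_i = γ_i p_j + α_i (1 - p_j) in
    closed form.  The denominator 1 - (α_1-γ_1)(α_2-γ_2) vanishes only
    when both |α_i - γ_i| = 1 with product +1 (e.g. tit-for-tat against
    tit-for-tat), where the long-run play depends on initial conditions.
    The formula is evaluated formally even for parameters outside the
    unit square (needed on the extended equilibrium curve).
    """
    d1 = s1.alpha - s1.gamma
    d2 = s2.alpha - s2.gamma
    denom = 1.0 - d1 * d2
    if abs(denom) < 1e-12:
        raise DegenerateChainError(
            "stationary distribution is not unique for this strategy pair "
            "(tit-for-tat-like cycle); fix the first-round convention instead"
        )
    p1 = (s1.alpha - s2.alpha * d1) / denom
    p2 = (s2.alpha - s1.alpha * d2) / denom
    return StationaryProfile(p1, p2)


def transition_matrix(s1: MarkovStrategy, s2: MarkovStrategy) -> np.ndarray:
    """Row-stochastic 4x4 transition matrix over joint states
    ``STATE_ORDER`` = (CC, CD, DC, DD).

    From previous joint moves (a, b), player 1 cooperates next with
    probability γ1 if b = C else α1, player 2 with probability γ2 if
    a = C else α2; the next moves are conditionally independent.
    """
    for s in (s1, s2):
        if not s.in_unit_square:
            raise ValueError(f"strategy {s} is outside the unit square")
    rows = []
    for a, b in (("C", "C"), ("C", "D"), ("D", "C"), ("D", "D")):
        q1 = s1.gamma if b == "C" else s1.alpha
        q2 = s2.gamma if a == "C" else s2.alpha
        rows.append(
            [q1 * q2, q1 * (1 - q2), (1 - q1) * q2, (1 - q1) * (1 - q2)]
        )
    return np.array(rows)


def stationary_joint(s1: MarkovStrategy, s2: MarkovStrategy) -> np.ndarray:
    """Stationary law of the joint chain over (CC, CD, DC, DD), computed
    from the left null space of the transition matrix.

    For interior strategies it equals the outer product of the marginals
    of ``stationary_cooperation`` (the stationary covariance of the two
    moves is zero).  Raises ``DegenerateChainError`` when the stationary
    law is not unique.
    """
    T = transition_matrix(s1, s2)
    A = T.T - np.eye(4)
    # unique stationary law <=> rank(T^T - I) == 3
    if np.linalg.matrix_rank(A, tol=1e-10) < 3:
        raise DegenerateChainError(
            "joint chain has multiple stationary laws (periodic or reducible)"
        )
    w, v = np.linalg.eig(T.T)
    idx = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, idx])
    pi = pi / pi.sum()
    return pi


def expected_payoff(
    p: StationaryProfile, payoffs: PDPayoffs = DEFAULT_PAYOFFS
) -> float:
    """Player 1's expected stage payoff under independent cooperation
    probabilities (p1, p2): the bilinear form
    R p1 p2 + S p1 (1-p2) + T (1-p1) p2 + P (1-p1)(1-p2), which for the
    default prizes is -4 p1 p2 - p1 + 9 p2 + 1."""
    p1, p2 = p.p1c, p.p2c
    return (
        payoffs.R * p1 * p2
        + payoffs.S * p1 * (1 - p2)
        + payoffs.T * (1 - p1) * p2
        + payoffs.P * (1 - p1) * (1 - p2)
    )


def foc_residual(s: MarkovStrategy, payoffs: PDPayoffs = DEFAULT_PAYOFFS) -> float:
    """First-order condition for a symmetric totally mixed equilibrium.

    Against an opponent playing (α, γ), player 1's stationary probability
    can be steered freely while the opponent responds along
    p2 = α + (γ - α) p1; the derivative of U1 along that line, evaluated
    at the symmetric stationary point p = α/(1 + α - γ), is returned.
    For the default prizes it reduces to -8(γ-α)p + 9(γ-α) - 4α - 1.
    Zero residual characterizes the equilibrium conic.
    """
    a, g = s.alpha, s.gamma
    if math.isclose(a, g, abs_tol=1e-12):
        raise ValueError(
            "gamma == alpha: the opponent's stationary response is flat and "
            "the first-order condition is degenerate"
        )
    B = payoffs.R - payoffs.S - payoffs.T + payoffs.P
    p = a / (1.0 + a - g)
    return B * p + (payoffs.S - payoffs.P) + (g - a) * (B * p + payoffs.T - payoffs.P)


def equilibrium_residual(
    alpha: float, gamma: float, payoffs: PDPayoffs = DEFAULT_PAYOFFS
) -> float:
    """Value of the equilibrium conic at (α, γ); zero iff the point is a
    symmetric totally mixed equilibrium.

    The conic is the first-order condition cleared of its denominator
    (multiplied by 1 + α - γ), with coefficients derived from the stage
    payoffs at run time; for the default prizes it is exactly
    5α² + 9γ² - 14αγ + 14α - 10γ + 1.
    """
    a, g = alpha, gamma
    B = payoffs.R - payoffs.S - payoffs.T + payoffs.P
    SP = payoffs.S - payoffs.P
    TP = payoffs.T - payoffs.P
    # foc_residual * (1 + a - g), with p (1 + a - g) = a, then negated so
    # that the default-payoff coefficients match the conic's printed form.
    cleared = B * a + SP * (1.0 + a - g) + (g - a) * (B * a + TP * (1.0 + a - g))
    return -cleared


def curve_alpha_given_gamma(
    gamma: float, payoffs: PDPayoffs = DEFAULT_PAYOFFS
) -> float:
    """Tolerance coordinate of the equilibrium curve at a given γ.

    Solves the conic as a quadratic in α and returns the LARGER root
    (the branch facing the empirical points).  For γ < 1/9 (default
    prizes) the larger root is slightly negative; it is still returned —
    the formal extension of the curve outside the unit square is what
    the deviation statistics are measured against.
    """
    r0 = equilibrium_residual(0.0, gamma, payoffs)
    r1 = equilibrium_residual(1.0, gamma, payoffs)
    rm1 = equilibrium_residual(-1.0, gamma, payoffs)
    a2 = (r1 + rm1) / 2.0 - r0
    a1 = (r1 - rm1) / 2.0
    a0 = r0
    disc = a1 * a1 - 4.0 * a2 * a0
    if disc < 0:
        raise ValueError(
            f"no real equilibrium tolerance at gamma = {gamma} (discriminant < 0)"
        )
    sq = math.sqrt(disc)
    roots = ((-a1 + sq) / (2.0 * a2), (-a1 - sq) / (2.0 * a2))
    return max(roots)


def max_tolerance_point(payoffs: PDPayoffs = DEFAULT_PAYOFFS) -> EquilibriumPoint:
    """The equilibrium point with maximum tolerance to defection.

    Obtained from the tangency condition ∂F/∂γ = 0 on the conic F = 0;
    with the default prizes this is closed form: α* = 7 - 3√5 ≈ 0.292,
    γ* = (5 + 7α*)/9 ≈ 0.783, the point the curve's before/after
    branches meet (rounds to (0.3, 0.8)).  For non-default prizes the
    point is located numerically on the curve.
    """
    if payoffs == DEFAULT_PAYOFFS:
        alpha = 7.0 - 3.0 * math.sqrt(5.0)
        gamma = (5.0 + 7.0 * alpha) / 9.0
        return EquilibriumPoint(alpha, gamma)
    gammas = np.linspace(1e-6, 1.0, 20001)
    alphas = np.array([curve_alpha_given_gamma(g, payoffs) for g in gammas])
    i = int(np.argmax(alphas))
    lo, hi = gammas[max(i - 1, 0)], gammas[min(i + 1, len(gammas) - 1)]
    from scipy.optimize import minimize_scalar

    res = minimize_scalar(
        lambda g: -curve_alpha_given_gamma(g, payoffs),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-12},
    )
    return EquilibriumPoint(-res.fun, float(res.x))


def best_response_check(
    eq: EquilibriumPoint,
    grid_step: float = 0.01,
    payoffs: PDPayoffs = DEFAULT_PAYOFFS,
) -> float:
    """Maximum unilateral payoff gain over a grid of memory-one
    deviations against an opponent holding the equilibrium strategy.

    For a true interior equilibrium with γ > α the payoff is concave in
    the deviator's induced stationary probability, so the gain is
    numerically zero; points off the curve yield strictly positive
    gains.
    """
    opp = MarkovStrategy(eq.alpha, eq.gamma)
    p_eq = stationary_cooperation(opp, opp)
    u_eq = expected_payoff(p_eq, payoffs)

    n = int(round(1.0 / grid_step)) + 1
    a1, g1 = np.meshgrid(np.linspace(0, 1, n), np.linspace(0, 1, n), indexing="ij")
    d1 = a1 - g1
    d2 = opp.alpha - opp.gamma
    denom = 1.0 - d1 * d2
    p1 = (a1 - opp.alpha * d1) / denom
    p2 = opp.alpha - d2 * p1  # = gamma2 p1 + alpha2 (1 - p1)
    u_dev = (
        payoffs.R * p1 * p2
        + payoffs.S * p1 * (1 - p2)
        + payoffs.T * (1 - p1) * p2
        + payoffs.P * (1 - p1) * (1 - p2)
    )
    return float(np.max(u_dev) - u_eq)


@dataclass(frozen=True)
class DeviationReport:
    """Distance and payoff-deviation statistics of one empirical point.

    ``distance`` is the signed horizontal gap alpha_exp - alpha_curve at
    equal reciprocal cooperation; ``deviation_pct`` is the percent
    payoff the deviating player loses relative to the same-γ symmetric
    equilibrium, the ε of the ε-equilibrium claim.  ``formal_extension``
    flags curve points outside the unit square (γ < 1/9 branch), where
    the equilibrium strategy is a formal continuation of the conic.
    """

    session_id: str | None
    stage: str | None
    alpha_exp: float
    gamma_exp: float
    alpha_curve: float
    distance: float
    u_eq: float
    u_dev: float
    deviation_pct: float
    formal_extension: bool = False


def deviation_report(
    alpha_exp: float,
    gamma_exp: float,
    payoffs: PDPayoffs = DEFAULT_PAYOFFS,
    session_id: str | None = None,
    stage: str | None = None,
) -> DeviationReport:
    """Measure one empirical (α, γ) point against the equilibrium curve.

    The same-γ curve point (α_c, γ) defines the reference equilibrium;
    the empirical point is treated as a unilateral deviation in
    tolerance by one player while the other holds (α_c, γ).  Reports the
    signed distance α_exp - α_c, the equilibrium payoff u_eq, the
    deviator's stationary payoff u_dev, and the relative loss
    100 (u_eq - u_dev)/u_eq.  Losses are not clamped: a negative value
    would indicate a profitable deviation.
    """
    if not 0.0 <= gamma_exp <= 1.0:
        raise ValueError(f"gamma_exp must be in [0, 1], got {gamma_exp}")
    alpha_curve = curve_alpha_given_gamma(gamma_exp, payoffs)
    eq_strategy = MarkovStrategy(alpha_curve, gamma_exp)
    dev_strategy = MarkovStrategy(alpha_exp, gamma_exp)
    u_eq = expected_payoff(stationary_cooperation(eq_strategy, eq_strategy), payoffs)
    u_dev = expected_payoff(
        stationary_cooperation(dev_strategy, eq_strategy), payoffs
    )
    return DeviationReport(
        session_id=session_id,
        stage=stage,
        alpha_exp=alpha_exp,
        gamma_exp=gamma_exp,
        alpha_curve=alpha_curve,
        distance=alpha_exp - alpha_curve,
        u_eq=u_eq,
        u_dev=u_dev,
        deviation_pct=100.0 * (u_eq - u_dev) / u_eq,
        formal_extension=not (0.0 <= alpha_curve <= 1.0),
    )
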