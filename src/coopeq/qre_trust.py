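"""Logit quantal-response equilibrium for the sequential Trust Game.

The Grantor sends k ∈ {0..10}; the transfer is tripled and the Grateful
returns n ∈ {0..3k}.  Payoffs are 10 - k + n for the Grantor and 3k - n
for the Grateful.  The QRE is built backward:

* the Grateful's return is a logit choice over own payoff 3k - n,
  p2(k, n) ∝ exp(λ(3k - n));
* the Grantor anticipates it, u1(k) = 10 - k + E[n | k];
* the trust level is a logit choice over u1, p1(k) ∝ exp(λ u1(k)).

Forecast means k(λ) = E[k] and n(λ) = E[n] under the joint p1·p2 are
compared with the observed session averages (k*, n*); λ is fitted by
minimizing the Euclidean distance between the two pairs.  At λ = 0 both
stages are uniform, giving k(0) = 5 and n(0) = 7.5 exactly; as λ → ∞
the model collapses to the subgame-perfect outcome k = n = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .qre_pd import logit_choice

__all__ = [
    "TrustObservation",
    "TrustQREModel",
    "gratitude_distribution",
    "expected_grantor_payoff",
    "trust_distribution",
    "forecast_trust_gratefulness",
    "fit_lambda_tg",
]

K_MAX = 10


@dataclass(frozen=True)
class TrustObservation:
    """Observed session averages of trust k* and gratefulness n*.

    n* <= 3 k* is not required pointwise: both are averages over rounds.
    """

    k_star: float
    n_star: float

    def __post_init__(self) -> None:
        if not 0 <= self.k_star <= K_MAX:
            raise ValueError(f"k_star must be in [0, {K_MAX}], got {self.k_star}")
        if self.n_star < 0:
            raise ValueError(f"n_star must be >= 0, got {self.n_star}")


def _check_k(k: int) -> int:
    if int(k) != k or not 0 <= k <= K_MAX:
        raise ValueError(f"trust level k must be an integer in [0, {K_MAX}], got {k}")
    return int(k)


def gratitude_distribution(k: int, lam: float) -> np.ndarray:
    """Logit distribution of the return n ∈ {0..3k} given trust k.

    The Grateful's own payoff from returning n is 3k - n, so mass decays
    geometrically in n at rate exp(-λ); for k = 0 this is the point mass
    on n = 0.
    """
    k = _check_k(k)
    payoffs = 3 * k - np.arange(3 * k + 1, dtype=float)
    return logit_choice(payoffs, lam)


def expected_grantor_payoff(k: int, lam: float) -> float:
    """Expected Grantor payoff u1(k) = 10 - k + E[n | k] under the
    Grateful's logit response."""
    k = _check_k(k)
    p2 = gratitude_distribution(k, lam)
    return 10.0 - k + float(p2 @ np.arange(3 * k + 1))


def trust_distribution(lam: float) -> np.ndarray:
    """Logit distribution of the trust level k ∈ {0..10} over u1(·; λ)."""
    u1 = np.array([expected_grantor_payoff(k, lam) for k in range(K_MAX + 1)])
    return logit_choice(u1, lam)


@dataclass(frozen=True)
class TrustQREModel:
    """The full QRE of the Trust Game at one precision λ."""

    lam: float
    p2: tuple[np.ndarray, ...]  # p2[k] is the return distribution given k
    u1: np.ndarray  # expected grantor payoffs, k = 0..10
    p1: np.ndarray  # trust distribution over k = 0..10

    @classmethod
    def solve(cls, lam: float) -> "TrustQREModel":
        p2 = tuple(gratitude_distribution(k, lam) for k in range(K_MAX + 1))
        u1 = np.array(
            [10.0 - k + float(p2[k] @ np.arange(3 * k + 1)) for k in range(K_MAX + 1)]
        )
        return cls(lam=lam, p2=p2, u1=u1, p1=logit_choice(u1, lam))

    def forecast(self) -> tuple[float, float]:
        k_mean = float(self.p1 @ np.arange(K_MAX + 1))
        n_mean = float(
            sum(
                self.p1[k] * (self.p2[k] @ np.arange(3 * k + 1))
                for k in range(K_MAX + 1)
            )
        )
        return k_mean, n_mean


def forecast_trust_gratefulness(lam: float) -> tuple[float, float]:
    """Model forecasts (k(λ), n(λ)): the mean trust under p1 and the mean
    return under the joint p1·p2."""
    return TrustQREModel.solve(lam).forecast()


def fit_lambda_tg(
    obs: TrustObservation,
    lam_max: float = 2.0,
    grid_step: float = 1e-3,
) -> float:
    """Precision λ whose forecasts best match an observed (k*, n*) pair.

    Minimizes the Euclidean distance ||(k(λ) - k*, n(λ) - n*)|| over
    λ ∈ [0, lam_max] by a dense grid scan (step ``grid_step``) followed
    by local refinement; grid ties break toward the smaller λ.
    """
    grid = np.arange(0.0, lam_max + grid_step / 2, grid_step)

    def dist(lam: float) -> float:
        k_hat, n_hat = forecast_trust_gratefulness(lam)
        return float(np.hypot(k_hat - obs.k_star, n_hat - obs.n_star))

    values = np.array([dist(lam) for lam in grid])
    best = int(np.argmin(values))  # argmin returns the first = smallest lam
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, len(grid) - 1)]
    if hi > lo:
        res = minimize_scalar(
            dist, bounds=(lo, hi), method="bounded", options={"xatol": 1e-9}
        )
        if res.fun < values[best]:
            return float(res.x)
    return float(grid[best])
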