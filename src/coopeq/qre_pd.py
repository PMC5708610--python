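"""Logit quantal-response equilibrium (QRE) for the one-shot Prisoner's
Dilemma.

Under a logit response with precision λ, a player cooperates with
probability σ_C = exp(λ u_C) / (exp(λ u_C) + exp(λ u_D)), where u_C and
u_D are the expected payoffs of cooperating and defecting against a
partner who cooperates with probability p.  In the symmetric QRE the
belief p equals the choice probability itself, giving the fixed point

    p = 1 / (1 + exp(λ (u_D(p) - u_C(p)))).

With the experiment's payoffs (T, R, P, S) = (10, 5, 1, 0) the payoff
gap is u_D - u_C = 4p + 1, and the fixed point inverts in closed form:
λ = ln((1 - p)/p) / (4p + 1).  At λ = 0 play is uniform (p = 0.5); as
λ → ∞ the QRE approaches the mutual-defection Nash equilibrium (p → 0).
Cooperation rates above 0.5 cannot be rationalized by any positive λ.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from scipy.optimize import brentq

from .games_core import DEFAULT_PAYOFFS, PDPayoffs

__all__ = ["logit_choice", "qre_cooperation_prob", "lambda_from_cooperation"]


def logit_choice(utilities, lam: float) -> np.ndarray:
    """Logit (softmax) choice probabilities at precision λ.

    Probabilities are proportional to exp(λ u_j); the computation shifts
    by the maximum utility for numerical stability.  λ = 0 gives the
    uniform distribution; large λ concentrates on the best action(s).
    """
    if lam < 0:
        raise ValueError(f"precision lam must be >= 0, got {lam}")
    u = np.asarray(utilities, dtype=float)
    if u.ndim != 1 or u.size == 0:
        raise ValueError("utilities must be a non-empty 1-D vector")
    if not np.all(np.isfinite(u)):
        raise ValueError("utilities must be finite")
    z = lam * (u - u.max())
    w = np.exp(z)
    return w / w.sum()


def _payoff_gap(p: float, payoffs: PDPayoffs) -> float:
    # u_D - u_C against a partner cooperating with probability p;
    # equals 4p + 1 for the default (10, 5, 1, 0) prizes.
    return ((payoffs.T - payoffs.R) - (payoffs.P - payoffs.S)) * p + (
        payoffs.P - payoffs.S
    )


def qre_cooperation_prob(
    lam: float, payoffs: PDPayoffs = DEFAULT_PAYOFFS, tol: float = 1e-12
) -> float:
    """Symmetric QRE cooperation probability p at precision λ.

    Solves p = 1 / (1 + exp(λ (u_D(p) - u_C(p)))) by bracketed root
    search on [0, 1].  In a PD the payoff gap u_D - u_C is positive and
    increasing in p, so the right-hand side is strictly decreasing and
    the root unique.
    """
    if lam < 0:
        raise ValueError(f"precision lam must be >= 0, got {lam}")

    def residual(p: float) -> float:
        return p - 1.0 / (1.0 + math.exp(lam * _payoff_gap(p, payoffs)))

    root = brentq(residual, 0.0, 1.0, xtol=1e-15, rtol=8.9e-16)
    assert abs(residual(root)) <= tol
    return root


def lambda_from_cooperation(p: float, payoffs: PDPayoffs = DEFAULT_PAYOFFS) -> float:
    """Precision λ whose symmetric QRE cooperation probability equals p.

    Closed-form inversion of the fixed point:
    λ = ln((1 - p)/p) / (u_D(p) - u_C(p)), i.e. ln((1-p)/p)/(4p + 1)
    for the default prizes.  Rates p >= 0.5 give λ <= 0, outside the
    QRE's domain of sensible precisions; a warning is raised because
    such data cannot be rationalized by noisy best response to the
    dominant action.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"cooperation rate must be strictly inside (0, 1), got {p}")
    lam = math.log((1.0 - p) / p) / _payoff_gap(p, payoffs)
    if lam <= 0:
        warnings.warn(
            f"cooperation rate {p} >= 0.5 implies a non-positive precision "
            f"(lam = {lam:.4g}); the QRE concept is not fully applicable",
            stacklevel=2,
        )
    return lam
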