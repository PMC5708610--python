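# Methods

## Games and payoffs

The stage game is a Prisoner's Dilemma with prizes T > R > P > S fixed
at (10, 5, 1, 0); `PDPayoffs` enforces the strict ordering and every
formula in the package derives its coefficients from the prize
structure at run time, so the printed default forms (4p + 1 payoff gap,
the −4p₁p₂ − p₁ + 9p₂ + 1 payoff, the 5α² + 9γ² − 14αγ + 14α − 10γ + 1
conic) are recovered as the special case rather than hard-coded.

The Trust Game endows the grantor with 10 points; a transfer k is
tripled and the grateful returns n ∈ [0, 3k]. Payoffs are 10 − k + n
and 3k − n. One published sentence transposes the grantor's formula
("10 − n + k" with the roles of k and n swapped); the implementation
follows the arithmetic that every other statement implies — keep
10 − k, receive n — under which the pie is conserved at 10 + 2k.

## QRE in the one-shot PD

Against a population cooperating with probability p, cooperation earns
u_C = Rp + S(1 − p) and defection u_D = Tp + P(1 − p). The symmetric
logit QRE solves p = 1/(1 + exp(λ(u_D − u_C))). The right-hand side is
strictly decreasing in p (u_D − u_C increases in p in a PD), so the
fixed point is unique; it is found by Brent's bracketed root search on
[0, 1] with residual below 1e−12. The inversion λ(p) is closed form.
Rates p ≥ 0.5 yield λ ≤ 0 and raise a warning rather than an error:
such data fall outside the concept's domain but the formal value is
still informative.

The per-session precision column is reproduced from the 3-decimal
published cooperation rates. For the lowest-cooperation session the
published precision was evidently computed from the unrounded rate; the
3-dp input cannot land closer than ≈0.0023 to it, and the corresponding
reproduction test documents this in its failure message rather than
loosening the band.

## QRE in the Trust Game

The model is solved backward exactly over the finite action sets (no
sampling): p₂(k, ·) is a logit over the grateful's payoff 3k − n,
u₁(k) = 10 − k + E[n|k], p₁ a logit over u₁ at the same λ, and the
forecast pair (k(λ), n(λ)) is the expectation of k under p₁ and of n
under the joint p₁·p₂. At λ = 0 both stages are uniform and the
forecasts are exactly (5, 7.5).

The published account fits λ "as close as possible" without naming a
metric; this package minimizes the Euclidean distance
‖(k(λ) − k*, n(λ) − n*)‖ over λ ∈ [0, 2] by a 1e−3 grid scan with
bounded local refinement, ties toward the smaller λ. This choice
reproduces all seven published (λ, forecast) rows: fitted λ within
±0.005 of print and forecasts at the *fitted* λ within ±0.005 of the
printed forecast columns. (The printed λ is itself rounded to 2 dp;
forecasts re-evaluated at the rounded λ drift by up to 0.11, which is
how one can tell the published forecasts were computed before
rounding.) The search ceiling of 2 is far above every fitted value
(max 0.344) and is configurable.

## Memory-one strategies in the iterated PD

A strategy (α, γ) reacts only to the partner's previous move. A pair of
strategies induces a 4-state Markov chain over joint moves; for
interior strategies the chain is ergodic and its stationary law is the
*product* of the marginal cooperation probabilities — the stationary
covariance c satisfies c = (γ₁ − α₁)(γ₂ − α₂)c and hence vanishes. The
closed-form marginals are therefore sufficient for long-run payoffs;
the eigenvector of the explicit transition matrix serves as an
independent oracle in the tests, not as the computational path.

Degenerate pairs (|α − γ| = 1 on both sides with product +1, e.g.
tit-for-tat against tit-for-tat) have no unique stationary law; the
package raises an explicit error pointing to the first-round
convention, and the simulator's default convention (cooperate in round
one) realizes the all-cooperate outcome for tit-for-tat pairs. The
convention is a visible parameter, never a silent default.

### The equilibrium conic

Against a fixed opponent (α, γ), a player's feasible stationary
probability p₁ can be steered across (0, 1) by their own strategy while
the opponent responds along p₂ = α + (γ − α)p₁. Long-run payoff is
quadratic in p₁ with leading coefficient (R − S − T + P)(γ − α) =
−4(γ − α): concave whenever the opponent is more reciprocal than
tolerant. Setting the derivative to zero at the symmetric stationary
point and clearing the denominator yields the conic; `foc_residual`
(the uncleaned derivative) and `equilibrium_residual` (the conic) agree
up to the factor −(1 + α − γ), which the tests assert as an algebraic
identity. The maximum-tolerance point follows from the tangency
condition ∂F/∂γ = 0, closed form α\* = 7 − 3√5, γ\* = (5 + 7α\*)/9 for
the default prizes. Concavity also justifies the grid-based
`best_response_check`: on the curve the maximal unilateral gain over a
101×101 strategy grid is numerically zero (≤ 1e−9).

### Distances and payoff deviations

Each session stage's estimated (α̂, γ̂) is compared with the curve point
of equal γ, taking the **larger** root of the conic-in-α. Below
γ = 1/9 the larger root is slightly negative; the formal root is used
anyway and flagged (`formal_extension`) — this extension of the curve
beyond the unit square is the only reading that reproduces the
published distance and deviation for the one low-reciprocity session.
The deviation statistic treats the empirical point as a unilateral
α-deviation against the curve strategy and reports the loss as a
percent of the equilibrium payoff; losses are not clamped, so a
profitable deviation would surface as a negative value (none occurs in
the series).

## Estimation from logs

Moves at round t ≥ 2 are classified by the move of the partner *actually
faced at t − 1* (not the current partner's history) — the literal
reading of a memory-one response under anonymous re-pairing. Round-1
moves are never classified; a missing previous-round record skips the
move with a logged warning. Estimators are exact integer ratios,
rounded only at report time. A zero denominator leaves the estimate
undefined (`None`), never zero. Cooperation levels include all rounds.
Comparisons against published 3-dp tables use a half-unit-in-last-place
absolute tolerance because the published tables round halves up while
IEEE round-half-even would disagree on exact halves (91/112 = 0.8125).

## Synthetic sessions

The PD generator emulates the experiment's two regimes: 12 players with
a fresh uniform random perfect matching each round (anonymous stage,
11 rounds) and fixed groups of four with within-group random matching
(post-socialization stage, 18 rounds); those defaults mirror the lab
design, and the long-horizon runs used for convergence checks override
only the round count. First-round behavior defaults to certain
cooperation, with a Bernoulli(p₀) option for robustness. All draws stem
from one seed through named substreams (pairing, moves, trust), so
adding a generator cannot shift another's stream; identical
configurations are byte-identical on disk.

What the generator does *not* emulate: learning or strategy drift
across rounds, heterogeneity across players within a session (available
by passing per-player strategies, but not part of any default), and any
causal model of the socialization procedure itself — strategies are
exogenous inputs. Passing tests therefore validate the estimation
machinery and the stationary theory, not the behavioral claim that
socialization changes strategies.

Validation problem sizes were chosen for tight Monte-Carlo error at
interactive runtimes: stationary-frequency checks use 12 players ×
2·10⁴ rounds (3-standard-error criterion), the independence check a
50 000-round two-player run (χ² at the 0.001 level), and the recovery
experiment 50 replications of 10⁴ rounds (bias < 0.01), plus a
200-replication run at the experiment's own 11 rounds that documents —
without asserting — the small-sample noise of the real design
(per-session RMSE ≈ 0.06 on α̂, ≈ 0.04 on γ̂).

## Numerical choices

* Fixed-point root search: Brent on [0, 1], xtol 1e−15; residual
  asserted ≤ 1e−12.
* Conic-in-α coefficients are extracted by evaluating the residual at
  α ∈ {0, 1, −1} (exact for a quadratic) so that non-default prizes
  need no re-derivation; complex roots raise a domain error (cannot
  occur for γ ∈ [0, 1] with the default prizes).
* The λ grid step for the TG fit (1e−3) is an order below the 2-dp
  print precision of the fitted values; local refinement then makes the
  self-consistency round-trip exact to 1e−3 or better.
* Stationary-law uniqueness is decided by the rank of Tᵀ − I at
  tolerance 1e−10 before the eigenvector is trusted.

## Interface

The package is a library plus narrative analysis drivers
(`analysis/01…04`); no console entry point is installed — for a
reproduction artifact the scripts and the importable functions are the
natural surface, and every table they print is produced by the same
functions the tests exercise.

## Known limitations

* Only the symmetric totally mixed equilibrium family is computed; no
  asymmetric equilibria, memory-2+ strategies, or evolutionary
  dynamics.
* The TG model is a plain logit QRE over both stages at one λ; no
  agent-QRE or subgame-perfect refinement.
* Published standard-deviation columns are carried as data, never
  recomputed (their exact definition is not stated).
* The ε-equilibrium statistic is relative payoff loss, matching the
  published tables; an absolute-loss variant is a one-line change on
  `DeviationReport` fields but is not wired into the summary.
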