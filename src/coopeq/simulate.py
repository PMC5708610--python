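"""Synthetic session generators emulating the experiments' structure.

PD sessions: an even number of players (12 in the experiments) play
memory-one strategies; each player cooperates in round t >= 2 with
probability γ if the partner they actually faced in round t-1
cooperated, else α.  Pairing is either a fresh uniform random perfect
matching every round (the anonymous stage) or random matching within
fixed groups of four (the post-socialization stage).  The first round
follows a convention: cooperate for sure (the default, matching the
tit-for-tat analysis) or an i.i.d. Bernoulli(p0) draw.

Trust Game sessions: logit agents at precision λ; every round draws the
trust level k from the QRE trust distribution p1(·; λ) and the return n
from the gratefulness distribution p2(k, ·; λ).

All draws descend from a single seed through named substreams
(pairing, moves, trust), so adding one generator never shifts another's
stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np

from .games_core import Move, RoundRecord, TrustRound, pd_payoff, DEFAULT_PAYOFFS, PDPayoffs
from .markov import MarkovStrategy
from .qre_trust import TrustQREModel

__all__ = [
    "SimulationConfig",
    "simulate_pd_session",
    "simulate_trust_session",
    "recovery_experiment",
    "RecoveryResult",
]

_SUBSTREAMS = ("pairing", "moves", "trust")


def _substreams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_SUBSTREAMS))
    return {name: np.random.default_rng(s) for name, s in zip(_SUBSTREAMS, children)}


@dataclass(frozen=True)
class SimulationConfig:
    """Configuration of one synthetic PD session stage.

    ``strategies`` is one strategy shared by all players or one per
    player.  ``pairing`` is ``random_rematch`` (anonymous stage) or
    ``fixed_group`` (groups of ``group_size`` formed once, in player
    order).  ``first_move_rule`` is ``always_cooperate`` or
    ``bernoulli`` with cooperation probability ``p0``.
    """

    n_players: int = 12
    strategies: Union[MarkovStrategy, Sequence[MarkovStrategy]] = field(
        default_factory=lambda: MarkovStrategy(0.3, 0.8)
    )
    rounds: int = 11
    pairing: str = "random_rematch"
    group_size: int = 4
    first_move_rule: str = "always_cooperate"
    p0: float = 0.5
    seed: int = 0
    session_id: str = "sim"
    stage: str | None = None

    def __post_init__(self) -> None:
        if self.n_players < 2 or self.n_players % 2:
            raise ValueError(f"n_players must be even and >= 2, got {self.n_players}")
        if self.rounds < 1:
            raise ValueError(f"rounds must be >= 1, got {self.rounds}")
        if self.pairing not in ("random_rematch", "fixed_group"):
            raise ValueError(f"unknown pairing scheme {self.pairing!r}")
        if self.pairing == "fixed_group" and self.n_players % self.group_size:
            raise ValueError("n_players must be divisible by group_size")
        if self.first_move_rule not in ("always_cooperate", "bernoulli"):
            raise ValueError(f"unknown first_move_rule {self.first_move_rule!r}")

    def strategy_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        if isinstance(self.strategies, MarkovStrategy):
            strategies = [self.strategies] * self.n_players
        else:
            strategies = list(self.strategies)
            if len(strategies) != self.n_players:
                raise ValueError(
                    f"need {self.n_players} strategies, got {len(strategies)}"
                )
        for s in strategies:
            if not s.in_unit_square:
                raise ValueError(f"strategy {s} is outside the unit square")
        alphas = np.array([s.alpha for s in strategies])
        gammas = np.array([s.gamma for s in strategies])
        return alphas, gammas

    @property
    def effective_stage(self) -> str:
        if self.stage is not None:
            return self.stage
        return "before" if self.pairing == "random_rematch" else "after"


def _draw_partners(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Partner index for each player in one round."""
    partner = np.empty(cfg.n_players, dtype=int)
    if cfg.pairing == "random_rematch":
        blocks = [rng.permutation(cfg.n_players)]
    else:
        blocks = [
            np.arange(i, i + cfg.group_size)[rng.permutation(cfg.group_size)]
            for i in range(0, cfg.n_players, cfg.group_size)
        ]
    for perm in blocks:
        for j in range(0, len(perm), 2):
            a, b = perm[j], perm[j + 1]
            partner[a], partner[b] = b, a
    return partner


def simulate_pd_session(
    cfg: SimulationConfig, payoffs: PDPayoffs = DEFAULT_PAYOFFS
) -> list[RoundRecord]:
    """Simulate one PD session stage; fully reproducible from cfg.seed."""
    rngs = _substreams(cfg.seed)
    alphas, gammas = cfg.strategy_arrays()
    n = cfg.n_players
    stage = cfg.effective_stage
    player_ids = [f"p{i + 1:02d}" for i in range(n)]

    records: list[RoundRecord] = []
    prev_partner_move: np.ndarray | None = None  # move faced in round t-1
    for t in range(1, cfg.rounds + 1):
        partner = _draw_partners(cfg, rngs["pairing"])
        if t == 1:
            if cfg.first_move_rule == "always_cooperate":
                coop = np.ones(n, dtype=bool)
            else:
                coop = rngs["moves"].random(n) < cfg.p0
        else:
            prob = np.where(prev_partner_move, gammas, alphas)
            coop = rngs["moves"].random(n) < prob
        moves = [Move.COOPERATE if c else Move.DEFECT for c in coop]
        for i in range(n):
            j = partner[i]
            records.append(
                RoundRecord(
                    session_id=cfg.session_id,
                    stage=stage,
                    round=t,
                    player_id=player_ids[i],
                    partner_id=player_ids[j],
                    move=moves[i],
                    points=pd_payoff(moves[i], moves[j], payoffs),
                )
            )
        prev_partner_move = coop[partner]
    return records


def simulate_trust_session(
    lam: float,
    rounds: int,
    seed: int,
    n_pairs: int = 1,
    session_id: str = "sim",
) -> list[TrustRound]:
    """Simulate Trust Game rounds with logit agents at precision λ.

    Each round, each of ``n_pairs`` grantor/grateful pairs draws
    k ~ p1(·; λ) and then n ~ p2(k, ·; λ).
    """
    if lam < 0:
        raise ValueError(f"precision lam must be >= 0, got {lam}")
    rng = _substreams(seed)["trust"]
    model = TrustQREModel.solve(lam)
    ks = np.arange(11)
    records: list[TrustRound] = []
    for t in range(1, rounds + 1):
        for pair in range(n_pairs):
            k = int(rng.choice(ks, p=model.p1))
            n = int(rng.choice(np.arange(3 * k + 1), p=model.p2[k]))
            records.append(
                TrustRound(
                    session_id=session_id,
                    round=t,
                    grantor_id=f"g{2 * pair + 1:02d}",
                    grateful_id=f"g{2 * pair + 2:02d}",
                    trust_k=k,
                    return_n=n,
                )
            )
    return records


@dataclass(frozen=True)
class RecoveryResult:
    """Monte-Carlo accuracy of the conditional-ratio strategy estimators."""

    true_alpha: float
    true_gamma: float
    rounds: int
    replications: int
    alpha_hats: np.ndarray
    gamma_hats: np.ndarray
    bias_alpha: float
    bias_gamma: float
    rmse_alpha: float
    rmse_gamma: float
    coverage_alpha: float  # share of reps with |hat - true| <= 3 SE
    coverage_gamma: float


def recovery_experiment(
    true_strategy: MarkovStrategy,
    rounds: int,
    replications: int,
    seed: int,
    n_players: int = 12,
    pairing: str = "random_rematch",
) -> RecoveryResult:
    """Estimate (α, γ) from simulated sessions and report bias, RMSE and
    3-standard-error coverage of the ratio estimators
    α̂ = Ntolerant/Ndefault, γ̂ = Nrecoop/Ncoop."""
    from .empirics import count_conditional_moves, estimate_strategy

    if not (0 < true_strategy.alpha < 1 and 0 < true_strategy.gamma < 1):
        raise ValueError("true strategy must be interior for recovery")
    seeds = np.random.SeedSequence(seed).generate_state(replications)
    a_hats, g_hats, a_cov, g_cov = [], [], [], []
    for rep_seed in seeds:
        cfg = SimulationConfig(
            n_players=n_players,
            strategies=true_strategy,
            rounds=rounds,
            pairing=pairing,
            seed=int(rep_seed % (2**31)),
        )
        log = simulate_pd_session(cfg)
        counts = count_conditional_moves(log)[(cfg.session_id, cfg.effective_stage)]
        a_hat, g_hat = estimate_strategy(counts)
        a_hats.append(a_hat)
        g_hats.append(g_hat)
        se_a = np.sqrt(a_hat * (1 - a_hat) / counts.n_default)
        se_g = np.sqrt(g_hat * (1 - g_hat) / counts.n_coop)
        a_cov.append(abs(a_hat - true_strategy.alpha) <= 3 * se_a)
        g_cov.append(abs(g_hat - true_strategy.gamma) <= 3 * se_g)
    a_hats = np.array(a_hats)
    g_hats = np.array(g_hats)
    return RecoveryResult(
        true_alpha=true_strategy.alpha,
        true_gamma=true_strategy.gamma,
        rounds=rounds,
        replications=replications,
        alpha_hats=a_hats,
        gamma_hats=g_hats,
        bias_alpha=float(a_hats.mean() - true_strategy.alpha),
        bias_gamma=float(g_hats.mean() - true_strategy.gamma),
        rmse_alpha=float(np.sqrt(np.mean((a_hats - true_strategy.alpha) ** 2))),
        rmse_gamma=float(np.sqrt(np.mean((g_hats - true_strategy.gamma) ** 2))),
        coverage_alpha=float(np.mean(a_cov)),
        coverage_gamma=float(np.mean(g_cov)),
    )
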