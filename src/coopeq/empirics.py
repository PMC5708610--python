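"""Estimation of memory-one strategies and cooperation levels from
session data, and the end-to-end reproduction of the published summary
tables.

The sufficient statistics for a session stage are four conditional move
counts: Ncoop (partner cooperated in the previous round), Nrecoop
(cooperative reply to that cooperation), Ndefault (partner defected in
the previous round) and Ntolerant (cooperative reply to that
defection).  The strategy estimators are the exact ratios
α̂ = Ntolerant/Ndefault and γ̂ = Nrecoop/Ncoop.

``run_full_analysis`` chains every step of the package on the packaged
fixture tables (or on user-supplied round logs): the QRE precision per
session, the Trust Game fits and forecasts, the (α, γ) estimates, the
signed tolerance distances to the symmetric equilibrium curve and the
percent payoff deviations, plus the headline summary (how many points
sit within the distance threshold, the maximum payoff deviation, and
the share of deviations at or below 0.5%).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .games_core import (
    DEFAULT_PAYOFFS,
    Move,
    PDPayoffs,
    RoundRecord,
    load_table2,
    load_table4,
    load_table5,
)
from .markov import DeviationReport, deviation_report
from .qre_pd import lambda_from_cooperation
from .qre_trust import TrustObservation, fit_lambda_tg, forecast_trust_gratefulness

__all__ = [
    "ConditionalCounts",
    "SessionEstimates",
    "AnalysisReport",
    "count_conditional_moves",
    "estimate_strategy",
    "cooperation_level",
    "run_full_analysis",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConditionalCounts:
    """Conditional move counts of one session stage."""

    n_coop: int
    n_recoop: int
    n_default: int
    n_tolerant: int

    def __post_init__(self) -> None:
        if min(self.n_coop, self.n_recoop, self.n_default, self.n_tolerant) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_recoop > self.n_coop:
            raise ValueError("n_recoop cannot exceed n_coop")
        if self.n_tolerant > self.n_default:
            raise ValueError("n_tolerant cannot exceed n_default")


@dataclass(frozen=True)
class SessionEstimates:
    """Per-session, per-stage estimates used by the report tables."""

    session_id: str
    stage: str
    alpha_hat: Optional[float]
    gamma_hat: Optional[float]
    coop_rate: Optional[float] = None
    lambda_hat: Optional[float] = None


def count_conditional_moves(
    log: Iterable[RoundRecord],
) -> dict[tuple[str, str], ConditionalCounts]:
    """Classify every move at round t >= 2 by the move of the player's
    round t-1 partner (the partner actually faced, who may differ from
    the current partner under anonymous re-pairing).

    Round-1 moves have no previous partner move and are never
    classified.  A move whose round t-1 record is missing is skipped
    with a logged warning.
    """
    by_key: dict[tuple[str, str], dict[tuple[int, str], RoundRecord]] = {}
    for rec in log:
        by_key.setdefault((rec.session_id, rec.stage), {})[
            (rec.round, rec.player_id)
        ] = rec

    out: dict[tuple[str, str], ConditionalCounts] = {}
    for key, idx in by_key.items():
        n_coop = n_recoop = n_default = n_tolerant = 0
        for (t, pid), rec in idx.items():
            if t < 2:
                continue
            prev = idx.get((t - 1, pid))
            prev_partner = idx.get((t - 1, prev.partner_id)) if prev else None
            if prev is None or prev_partner is None:
                logger.warning(
                    "no round %d record for player %s in %s; move skipped",
                    t - 1,
                    pid,
                    key,
                )
                continue
            replied_coop = rec.move is Move.COOPERATE
            if prev_partner.move is Move.COOPERATE:
                n_coop += 1
                n_recoop += replied_coop
            else:
                n_default += 1
                n_tolerant += replied_coop
        out[key] = ConditionalCounts(n_coop, n_recoop, n_default, n_tolerant)
    return out


def estimate_strategy(
    c: ConditionalCounts,
) -> tuple[Optional[float], Optional[float]]:
    """Ratio estimators (α̂, γ̂) = (Ntolerant/Ndefault, Nrecoop/Ncoop).

    A zero denominator leaves the corresponding estimate undefined
    (None), never zero.
    """
    alpha_hat = c.n_tolerant / c.n_default if c.n_default > 0 else None
    gamma_hat = c.n_recoop / c.n_coop if c.n_coop > 0 else None
    return alpha_hat, gamma_hat


def cooperation_level(
    log: Iterable[RoundRecord],
) -> dict[tuple[str, str], float]:
    """Fraction of cooperative moves per (session, stage), all rounds
    included."""
    coop: dict[tuple[str, str], list[int]] = {}
    for rec in log:
        c, n = coop.setdefault((rec.session_id, rec.stage), [0, 0])
        coop[(rec.session_id, rec.stage)] = [
            c + (rec.move is Move.COOPERATE),
            n + 1,
        ]
    if not coop:
        raise ValueError("empty log: cooperation level undefined")
    return {key: c / n for key, (c, n) in coop.items()}


@dataclass(frozen=True)
class AnalysisReport:
    """Bundle of replicated summary tables and the headline statistics.

    ``table2``: per-session pre-socialization cooperation with the QRE
    precision from the closed-form inversion; ``series`` holds the
    series-average cooperation and its precision.  ``table4``: Trust
    Game fits and forecasts.  ``table6``: (α̂, γ̂) per session/stage.
    ``table7``: signed tolerance distances to the equilibrium curve.
    ``table8``: percent payoff deviations.  ``summary``: threshold
    counts and extreme deviations.
    """

    table2: pd.DataFrame
    series: dict
    table4: pd.DataFrame
    table6: pd.DataFrame
    table7: pd.DataFrame
    table8: pd.DataFrame
    deviations: Sequence[DeviationReport]
    summary: dict


def _counts_frame_from_logs(log: Sequence[RoundRecord]) -> pd.DataFrame:
    counts = count_conditional_moves(log)
    rows = [
        {
            "session_id": sid,
            "stage": stage,
            "n_coop": c.n_coop,
            "n_recoop": c.n_recoop,
            "n_default": c.n_default,
            "n_tolerant": c.n_tolerant,
        }
        for (sid, stage), c in sorted(counts.items())
    ]
    return pd.DataFrame(rows)


def run_full_analysis(
    round_log: Optional[Sequence[RoundRecord]] = None,
    trust_observations: Optional[dict[str, TrustObservation]] = None,
    payoffs: PDPayoffs = DEFAULT_PAYOFFS,
    distance_threshold: float = 0.1,
    small_deviation_pct: float = 0.5,
    lam_max: float = 2.0,
) -> AnalysisReport:
    """Run the complete analysis chain.

    Without arguments the packaged fixture tables are analyzed (the
    published session summaries); a ``round_log`` replaces the fixture
    cooperation levels and conditional counts, and ``trust_observations``
    (session -> observed (k*, n*)) replaces the fixture Trust Game
    averages.
    """
    # --- cooperation levels and QRE precision (pre-socialization) -----
    if round_log is None:
        t2 = load_table2()
        coop = t2[["session_id", "coop_mean"]].copy()
        counts_df = load_table5()
    else:
        levels = cooperation_level(round_log)
        coop = pd.DataFrame(
            [
                {"session_id": sid, "stage": stage, "coop_mean": level}
                for (sid, stage), level in sorted(levels.items())
            ]
        )
        coop = coop[coop["stage"] == "before"][["session_id", "coop_mean"]]
        counts_df = _counts_frame_from_logs(round_log)

    table2 = coop.copy()
    table2["lam"] = [
        lambda_from_cooperation(p, payoffs) if 0 < p < 1 else np.nan
        for p in table2["coop_mean"]
    ]
    mean_coop = float(table2["coop_mean"].mean())
    series = {
        "mean_cooperation": mean_coop,
        "lam_at_mean": lambda_from_cooperation(mean_coop, payoffs),
    }

    # --- Trust Game fits and forecasts --------------------------------
    if trust_observations is None:
        t4 = load_table4()
        trust_observations = {
            row.session_id: TrustObservation(row.trust_mean, row.grat_mean)
            for row in t4.itertuples()
        }
    t4_rows = []
    for sid, obs in trust_observations.items():
        lam_fit = fit_lambda_tg(obs, lam_max=lam_max)
        k_hat, n_hat = forecast_trust_gratefulness(lam_fit)
        t4_rows.append(
            {
                "session_id": sid,
                "trust_mean": obs.k_star,
                "grat_mean": obs.n_star,
                "lam": lam_fit,
                "forecast_trust": k_hat,
                "forecast_grat": n_hat,
            }
        )
    table4 = pd.DataFrame(t4_rows)

    # --- strategy estimates and deviation statistics -------------------
    t6_rows, t7_rows, t8_rows, reports = [], [], [], []
    for row in counts_df.itertuples():
        c = ConditionalCounts(row.n_coop, row.n_recoop, row.n_default, row.n_tolerant)
        alpha_hat, gamma_hat = estimate_strategy(c)
        t6_rows.append(
            {
                "session_id": row.session_id,
                "stage": row.stage,
                "alpha": alpha_hat,
                "gamma": gamma_hat,
            }
        )
        if alpha_hat is None or gamma_hat is None:
            logger.warning(
                "undefined strategy estimate for %s/%s; excluded from the "
                "deviation tables",
                row.session_id,
                row.stage,
            )
            continue
        rep = deviation_report(
            alpha_hat,
            gamma_hat,
            payoffs,
            session_id=row.session_id,
            stage=row.stage,
        )
        reports.append(rep)
        t7_rows.append(
            {
                "session_id": row.session_id,
                "stage": row.stage,
                "alpha_curve": rep.alpha_curve,
                "distance": rep.distance,
                "within_threshold": abs(rep.distance) < distance_threshold,
            }
        )
        t8_rows.append(
            {
                "session_id": row.session_id,
                "stage": row.stage,
                "u_eq": rep.u_eq,
                "u_dev": rep.u_dev,
                "deviation_pct": rep.deviation_pct,
            }
        )
    table6 = pd.DataFrame(t6_rows)
    table7 = pd.DataFrame(t7_rows)
    table8 = pd.DataFrame(t8_rows)

    dev = table8["deviation_pct"].to_numpy() if len(table8) else np.array([])
    summary = {
        "n_points": int(len(table7)),
        "n_within_threshold": int(table7["within_threshold"].sum())
        if len(table7)
        else 0,
        "distance_threshold": distance_threshold,
        "max_deviation_pct": float(dev.max()) if dev.size else np.nan,
        "n_small_deviation": int((dev <= small_deviation_pct).sum()),
        "share_small_deviation": float((dev <= small_deviation_pct).mean())
        if dev.size
        else np.nan,
        "small_deviation_pct": small_deviation_pct,
    }
    return AnalysisReport(
        table2=table2,
        series=series,
        table4=table4,
        table6=table6,
        table7=table7,
        table8=table8,
        deviations=reports,
        summary=summary,
    )
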