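"""Shared domain types for the cooperation experiments.

This module defines the payoff structure of the one-shot Prisoner's
Dilemma (PD), the moves, round-level session records for the PD and the
Trust Game (TG), and the CSV log dialects used throughout the package.
It also ships the session-level summary tables of the experiment series
(average cooperation, average trust/gratefulness, and conditional move
counts) as packaged fixtures.

Log dialects
------------
PD round logs are comma-separated UTF-8 with header::

    session_id,stage,round,player_id,partner_id,move,points

``move`` is a single character ``C``/``D``; ``points`` is optional on
input and recomputed from the pair of moves when absent.  Trust-game
logs use::

    session_id,round,grantor_id,grateful_id,trust_k,return_n
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd

__all__ = [
    "Move",
    "PDPayoffs",
    "DEFAULT_PAYOFFS",
    "RoundRecord",
    "TrustRound",
    "LogFormatError",
    "LogConsistencyError",
    "pd_payoff",
    "trust_payoffs",
    "read_round_log",
    "write_round_log",
    "read_trust_log",
    "write_trust_log",
    "load_table2",
    "load_table3",
    "load_table4",
    "load_table5",
]

STAGES = ("before", "after")


class Move(Enum):
    """A move in the Prisoner's Dilemma (cooperate or defect)."""

    COOPERATE = "C"
    DEFECT = "D"

    @classmethod
    def from_str(cls, s: str) -> "Move":
        try:
            return cls(s.strip().upper())
        except ValueError:
            raise ValueError(f"move must be 'C' or 'D', got {s!r}") from None


@dataclass(frozen=True)
class PDPayoffs:
    """Prisoner's Dilemma prizes T > R > P > S.

    T is the temptation payoff (defect against a cooperator), R the
    reward for mutual cooperation, P the punishment for mutual
    defection, and S the sucker payoff (cooperate against a defector).
    The experiments used (T, R, P, S) = (10, 5, 1, 0).
    """

    T: float = 10.0
    R: float = 5.0
    P: float = 1.0
    S: float = 0.0

    def __post_init__(self) -> None:
        if not (self.T > self.R > self.P > self.S):
            raise ValueError(
                f"payoffs must satisfy T > R > P > S, got "
                f"({self.T}, {self.R}, {self.P}, {self.S})"
            )


DEFAULT_PAYOFFS = PDPayoffs()


def pd_payoff(
    my_move: Move, partner_move: Move, payoffs: PDPayoffs = DEFAULT_PAYOFFS
) -> float:
    """Points earned by a player given both moves of the round."""
    if my_move is Move.COOPERATE:
        return payoffs.R if partner_move is Move.COOPERATE else payoffs.S
    return payoffs.T if partner_move is Move.COOPERATE else payoffs.P


@dataclass(frozen=True, slots=True)
class RoundRecord:
    """One player's move in one round of one PD session stage."""

    session_id: str
    stage: str
    round: int
    player_id: str
    partner_id: str
    move: Move
    points: float | None = None

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}, got {self.stage!r}")
        if self.round < 1:
            raise ValueError(f"round must be >= 1, got {self.round}")


@dataclass(frozen=True, slots=True)
class TrustRound:
    """One Trust Game interaction: the Grantor sends k in {0..10}, the
    amount is tripled, and the Grateful returns n in {0..3k}."""

    session_id: str
    round: int
    grantor_id: str
    grateful_id: str
    trust_k: int
    return_n: int

    def __post_init__(self) -> None:
        if not 0 <= self.trust_k <= 10:
            raise ValueError(f"trust_k must be in [0, 10], got {self.trust_k}")
        if not 0 <= self.return_n <= 3 * self.trust_k:
            raise ValueError(
                f"return_n must be in [0, {3 * self.trust_k}], got {self.return_n}"
            )


def trust_payoffs(round_: TrustRound) -> tuple[int, int]:
    """Points of (grantor, grateful): grantor keeps 10 - k and receives
    n back; the grateful keeps 3k - n of the tripled transfer.

    The pie is conserved: the payoffs sum to 10 + 2k.
    """
    k, n = round_.trust_k, round_.return_n
    if not 0 <= n <= 3 * k:  # re-check for callers bypassing the dataclass
        raise ValueError(f"return_n must be in [0, {3 * k}], got {n}")
    return 10 - k + n, 3 * k - n


class LogFormatError(ValueError):
    """A session log row could not be parsed."""


class LogConsistencyError(ValueError):
    """A parsed session log violates a structural invariant."""


_ROUND_HEADER = ["session_id", "stage", "round", "player_id", "partner_id", "move"]
_TRUST_HEADER = ["session_id", "round", "grantor_id", "grateful_id", "trust_k", "return_n"]


def read_round_log(
    path: Union[str, Path], payoffs: PDPayoffs = DEFAULT_PAYOFFS
) -> list[RoundRecord]:
    """Read and validate a PD round log.

    Validation: the pairing within each (session, stage, round) must be
    an involution (my partner's partner is me), each player appears at
    most once per round, and the points column -- when present -- must
    equal the PD payoff implied by the pair of moves.  The points column
    is recomputed when absent.
    """
    path = Path(path)
    records: list[RoundRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise LogFormatError(f"{path}: empty file, expected header")
        fields = [f.strip() for f in reader.fieldnames]
        missing = [c for c in _ROUND_HEADER if c not in fields]
        if missing:
            raise LogFormatError(f"{path}: header is missing columns {missing}")
        has_points = "points" in fields
        for i, row in enumerate(reader, start=2):
            try:
                points = None
                if has_points and row.get("points") not in (None, ""):
                    points = float(row["points"])
                rec = RoundRecord(
                    session_id=row["session_id"],
                    stage=row["stage"],
                    round=int(row["round"]),
                    player_id=row["player_id"],
                    partner_id=row["partner_id"],
                    move=Move.from_str(row["move"]),
                    points=points,
                )
            except (KeyError, TypeError, ValueError) as exc:
                raise LogFormatError(f"{path}: row {i}: {exc}") from exc
            records.append(rec)
    _validate_round_log(records, payoffs, source=str(path))
    return _with_points(records, payoffs)


def _validate_round_log(
    records: Sequence[RoundRecord], payoffs: PDPayoffs, source: str = "<log>"
) -> None:
    by_round: dict[tuple[str, str, int], dict[str, RoundRecord]] = {}
    for rec in records:
        key = (rec.session_id, rec.stage, rec.round)
        group = by_round.setdefault(key, {})
        if rec.player_id in group:
            raise LogConsistencyError(
                f"{source}: duplicate record for player {rec.player_id!r} in "
                f"session {rec.session_id!r} stage {rec.stage!r} round {rec.round}"
            )
        group[rec.player_id] = rec
    for key, group in by_round.items():
        for pid, rec in group.items():
            partner = group.get(rec.partner_id)
            if partner is None or partner.partner_id != pid:
                raise LogConsistencyError(
                    f"{source}: pairing is not an involution for player {pid!r} "
                    f"in session/stage/round {key}"
                )
            if rec.points is not None:
                expected = pd_payoff(rec.move, partner.move, payoffs)
                if abs(rec.points - expected) > 1e-9:
                    raise LogConsistencyError(
                        f"{source}: points {rec.points} for player {pid!r} in "
                        f"{key} do not match moves (expected {expected})"
                    )


def _with_points(
    records: Sequence[RoundRecord], payoffs: PDPayoffs
) -> list[RoundRecord]:
    by_round: dict[tuple[str, str, int], dict[str, Move]] = {}
    for rec in records:
        by_round.setdefault((rec.session_id, rec.stage, rec.round), {})[
            rec.player_id
        ] = rec.move
    out = []
    for rec in records:
        if rec.points is None:
            partner_move = by_round[(rec.session_id, rec.stage, rec.round)][
                rec.partner_id
            ]
            rec = RoundRecord(
                rec.session_id,
                rec.stage,
                rec.round,
                rec.player_id,
                rec.partner_id,
                rec.move,
                pd_payoff(rec.move, partner_move, payoffs),
            )
        out.append(rec)
    return out


def write_round_log(records: Iterable[RoundRecord], path: Union[str, Path]) -> None:
    """Write a PD round log in the package's CSV dialect."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_ROUND_HEADER + ["points"])
        for rec in records:
            pts = "" if rec.points is None else format(rec.points, "g")
            writer.writerow(
                [
                    rec.session_id,
                    rec.stage,
                    rec.round,
                    rec.player_id,
                    rec.partner_id,
                    rec.move.value,
                    pts,
                ]
            )


def read_trust_log(path: Union[str, Path]) -> list[TrustRound]:
    """Read a Trust Game log; per-row bounds (0 <= n <= 3k) are enforced."""
    path = Path(path)
    records: list[TrustRound] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise LogFormatError(f"{path}: empty file, expected header")
        missing = [c for c in _TRUST_HEADER if c not in reader.fieldnames]
        if missing:
            raise LogFormatError(f"{path}: header is missing columns {missing}")
        for i, row in enumerate(reader, start=2):
            try:
                records.append(
                    TrustRound(
                        session_id=row["session_id"],
                        round=int(row["round"]),
                        grantor_id=row["grantor_id"],
                        grateful_id=row["grateful_id"],
                        trust_k=int(row["trust_k"]),
                        return_n=int(row["return_n"]),
                    )
                )
            except (KeyError, TypeError, ValueError) as exc:
                raise LogFormatError(f"{path}: row {i}: {exc}") from exc
    return records


def write_trust_log(records: Iterable[TrustRound], path: Union[str, Path]) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_TRUST_HEADER)
        for rec in records:
            writer.writerow(
                [
                    rec.session_id,
                    rec.round,
                    rec.grantor_id,
                    rec.grateful_id,
                    rec.trust_k,
                    rec.return_n,
                ]
            )


def _load_fixture(name: str) -> pd.DataFrame:
    with resources.files("coopeq").joinpath(f"data/{name}").open("rb") as fh:
        return pd.read_csv(fh)


def load_table2() -> pd.DataFrame:
    """Per-session average pre-socialization cooperation levels (with the
    published logit precision values)."""
    return _load_fixture("table2.csv")


def load_table3() -> pd.DataFrame:
    """Per-session average post-socialization cooperation levels."""
    return _load_fixture("table3.csv")


def load_table4() -> pd.DataFrame:
    """Per-session average trust and gratefulness in the Trust Game, with
    the published fitted precision and model forecasts."""
    return _load_fixture("table4.csv")


def load_table5() -> pd.DataFrame:
    """Conditional move counts (Ncoop, Nrecoop, Ndefault, Ntolerant) per
    session and stage."""
    return _load_fixture("table5.csv")
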