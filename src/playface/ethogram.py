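"""Data model and I/O for ethograms, play sessions and behavioral event logs.

A *play session* is a dyadic bout of play-fighting: an ordered sequence of
timed behavioral pattern events (each classified offensive / defensive /
neutral by the species ethogram) interleaved with facial-expression events
(Play Face, PF, lower teeth exposed; Full Play Face, FPF, upper and lower
teeth exposed). Times are real-valued seconds from session start.

The module ships two plain-text fixtures: the gorilla play ethogram
(pattern -> category) and the composition table of the two study groups
(per-individual observation hours, session counts and PF/FPF totals).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CATEGORIES",
    "Ethogram",
    "PatternEvent",
    "ExpressionEvent",
    "PlaySession",
    "IndividualSummary",
    "ValidationError",
    "load_ethogram",
    "packaged_ethogram",
    "packaged_group_table",
    "group_table_to_summaries",
    "load_sessions",
    "write_sessions",
    "session_duration_stats",
    "rates_per_session",
]

CATEGORIES = ("offensive", "defensive", "neutral")

EVENT_LOG_COLUMNS = [
    "session_id", "group", "player_a", "player_b", "event_kind", "time_s",
    "offset_s", "actor", "target", "pattern", "expr_type", "perception",
]


class ValidationError(ValueError):
    """Raised when an ethogram or event log violates the data contract."""


def _norm(name: str) -> str:
    return " ".join(str(name).strip().lower().split())


@dataclass(frozen=True)
class Ethogram:
    """Catalog of behavioral patterns with their offensive/defensive/neutral
    classification. Pattern lookup is case-insensitive after trimming."""

    entries: dict[str, str]

    def __post_init__(self):
        if not self.entries:
            raise ValidationError("ethogram is empty")
        normed: dict[str, str] = {}
        for pat, cat in self.entries.items():
            key = _norm(pat)
            if key in normed:
                raise ValidationError(f"duplicate pattern {pat!r}")
            if cat not in CATEGORIES:
                raise ValidationError(
                    f"pattern {pat!r}: category {cat!r} not in {CATEGORIES}")
            normed[key] = cat
        object.__setattr__(self, "entries", normed)

    def __contains__(self, pattern: str) -> bool:
        return _norm(pattern) in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def category(self, pattern: str) -> str:
        key = _norm(pattern)
        if key not in self.entries:
            raise KeyError(f"pattern {pattern!r} not in ethogram")
        return self.entries[key]


@dataclass(frozen=True)
class PatternEvent:
    """One behavioral pattern occurrence. ``target`` is None for patterns
    performed alone (e.g. pirouetting)."""

    time: float
    actor: str
    target: Optional[str]
    pattern: str
    category: str

    def __post_init__(self):
        if self.time < 0:
            raise ValidationError(f"negative event time {self.time}")
        if self.target is not None and self.actor == self.target:
            raise ValidationError(f"actor == target ({self.actor!r})")
        if self.category not in CATEGORIES:
            raise ValidationError(f"bad category {self.category!r}")


@dataclass(frozen=True)
class ExpressionEvent:
    """A PF or FPF emission with onset/offset and the annotation of whether
    the partner could perceive it (frontal / lateral / blind / unknown)."""

    onset: float
    offset: float
    emitter: str
    expr_type: str
    partner_perception: str = "unknown"

    def __post_init__(self):
        if self.offset < self.onset:
            raise ValidationError(
                f"expression offset {self.offset} < onset {self.onset}")
        if self.expr_type not in ("PF", "FPF"):
            raise ValidationError(f"expr_type must be PF or FPF, got {self.expr_type!r}")
        if self.partner_perception not in ("frontal", "lateral", "blind", "unknown"):
            raise ValidationError(
                f"bad perception annotation {self.partner_perception!r}")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class PlaySession:
    """One dyadic play session with its ordered pattern and expression
    events. ``start``/``end`` are in the same clock as event times."""

    session_id: str
    group_id: str
    player_a: str
    player_b: str
    start: float
    end: float
    pattern_events: list[PatternEvent] = field(default_factory=list)
    expression_events: list[ExpressionEvent] = field(default_factory=list)

    def __post_init__(self):
        if self.player_a == self.player_b:
            raise ValidationError("a session needs two distinct players")
        if self.end <= self.start:
            raise ValidationError("session duration must be positive")
        self.pattern_events = sorted(self.pattern_events, key=lambda e: e.time)
        self.expression_events = sorted(self.expression_events, key=lambda e: e.onset)
        players = {self.player_a, self.player_b}
        for ev in self.pattern_events:
            if ev.actor not in players:
                raise ValidationError(
                    f"session {self.session_id}: actor {ev.actor!r} is not a player")
            if not self.start <= ev.time <= self.end:
                raise ValidationError(
                    f"session {self.session_id}: event at {ev.time} outside bounds")
        for ev in self.expression_events:
            if ev.emitter not in players:
                raise ValidationError(
                    f"session {self.session_id}: emitter {ev.emitter!r} is not a player")

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def players(self) -> tuple[str, str]:
        return (self.player_a, self.player_b)

    def partner_of(self, individual: str) -> str:
        if individual == self.player_a:
            return self.player_b
        if individual == self.player_b:
            return self.player_a
        raise KeyError(f"{individual!r} is not a player of {self.session_id}")


@dataclass(frozen=True)
class IndividualSummary:
    """Per-individual observation effort and expression counts."""

    individual: str
    n_sessions: int
    n_pf: int
    n_fpf: int
    hours_observed: float = float("nan")
    group: Optional[str] = None

    def __post_init__(self):
        if min(self.n_sessions, self.n_pf, self.n_fpf) < 0:
            raise ValidationError("counts must be non-negative")


# ---------------------------------------------------------------------------
# loaders
# ---------------------------------------------------------------------------

def load_ethogram(path) -> Ethogram:
    """Read a two-column (pattern, category) TSV into an Ethogram.

    Unknown categories and duplicate patterns are rejected with the
    offending row named.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: empty ethogram file") from None
    missing = {"pattern", "category"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    if df.empty:
        raise ValidationError(f"{path}: ethogram has no rows")
    entries: dict[str, str] = {}
    for i, row in df.iterrows():
        pat, cat = _norm(row["pattern"]), _norm(row["category"])
        if cat not in CATEGORIES:
            raise ValidationError(
                f"{path} row {i + 2}: pattern {row['pattern']!r} has unknown "
                f"category {row['category']!r}")
        if pat in entries:
            raise ValidationError(
                f"{path} row {i + 2}: duplicate pattern {row['pattern']!r}")
        entries[pat] = cat
    return Ethogram(entries)


def _data_path(name: str) -> Path:
    return Path(resources.files("playface.data") / name)


def packaged_ethogram() -> Ethogram:
    """The gorilla play ethogram shipped with the package."""
    return load_ethogram(_data_path("ethogram_gorilla.tsv"))


def packaged_group_table() -> pd.DataFrame:
    """Composition of the two study groups (VDS and BEA): sex, age,
    observation hours, session counts and PF/FPF totals per individual."""
    return pd.read_csv(_data_path("group_composition.tsv"), sep="\t")


def group_table_to_summaries(df: pd.DataFrame) -> list[IndividualSummary]:
    return [
        IndividualSummary(individual=row["individual"],
                          n_sessions=int(row["n_sessions"]),
                          n_pf=int(row["n_pf"]), n_fpf=int(row["n_fpf"]),
                          hours_observed=float(row["hours_observed"]),
                          group=row.get("group"))
        for _, row in df.iterrows()
    ]


def _blank(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v)) or str(v).strip() == ""


def load_sessions(path, ethogram: Ethogram) -> list[PlaySession]:
    """Read a long-format event-log TSV into PlaySession objects.

    One row per event; ``event_kind`` distinguishes behavioral patterns from
    PF/FPF expressions. Rows are grouped by ``session_id``; categories are
    attached from the ethogram; rows with unknown patterns are rejected with
    their file row numbers. Session ``start`` is 0 and ``end`` is the latest
    event time/offset in the session.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(EVENT_LOG_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    sessions: list[PlaySession] = []
    bad_rows = [i + 2 for i, row in df.iterrows()
                if row["event_kind"] == "pattern" and row["pattern"] not in ethogram]
    if bad_rows:
        raise ValidationError(f"{path}: unknown patterns at rows {bad_rows}")
    for sid, grp in df.groupby("session_id", sort=False):
        head = grp.iloc[0]
        patterns, expressions = [], []
        for _, row in grp.iterrows():
            t = float(row["time_s"])
            if row["event_kind"] == "pattern":
                target = None if _blank(row["target"]) else row["target"]
                patterns.append(PatternEvent(
                    time=t, actor=row["actor"], target=target,
                    pattern=_norm(row["pattern"]),
                    category=ethogram.category(row["pattern"])))
            elif row["event_kind"] == "expression":
                perception = "unknown" if _blank(row["perception"]) else row["perception"]
                expressions.append(ExpressionEvent(
                    onset=t, offset=float(row["offset_s"]), emitter=row["actor"],
                    expr_type=row["expr_type"], partner_perception=perception))
            else:
                raise ValidationError(
                    f"{path}: unknown event_kind {row['event_kind']!r} in session {sid}")
        end = max([e.time for e in patterns] + [e.offset for e in expressions])
        sessions.append(PlaySession(
            session_id=str(sid), group_id=head["group"],
            player_a=head["player_a"], player_b=head["player_b"],
            start=0.0, end=float(end),
            pattern_events=patterns, expression_events=expressions))
    return sessions


def write_sessions(sessions: Iterable[PlaySession], path) -> None:
    """Write sessions back to the long-format event-log TSV."""
    rows = []
    for s in sessions:
        events: list[tuple[float, dict]] = []
        for ev in s.pattern_events:
            events.append((ev.time, {
                "event_kind": "pattern", "time_s": ev.time, "offset_s": "",
                "actor": ev.actor, "target": ev.target or "",
                "pattern": ev.pattern, "expr_type": "", "perception": ""}))
        for ev in s.expression_events:
            events.append((ev.onset, {
                "event_kind": "expression", "time_s": ev.onset,
                "offset_s": ev.offset, "actor": ev.emitter, "target": "",
                "pattern": "", "expr_type": ev.expr_type,
                "perception": ev.partner_perception}))
        for _, rec in sorted(events, key=lambda x: x[0]):
            rows.append({"session_id": s.session_id, "group": s.group_id,
                         "player_a": s.player_a, "player_b": s.player_b, **rec})
    pd.DataFrame(rows, columns=EVENT_LOG_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# descriptive statistics
# ---------------------------------------------------------------------------

def session_duration_stats(sessions: Sequence[PlaySession]) -> dict:
    """Mean, SE (sd/sqrt(n)), min and max of session durations in seconds."""
    if not sessions:
        raise ValueError("need at least one session")
    d = np.array([s.duration for s in sessions], dtype=float)
    se = float(d.std(ddof=1) / math.sqrt(len(d))) if len(d) > 1 else float("nan")
    return {"n": len(d), "mean": float(d.mean()), "se": se,
            "min": float(d.min()), "max": float(d.max())}


def rates_per_session(summaries: Sequence[IndividualSummary],
                      zero_convention: str = "zero") -> pd.DataFrame:
    """Per-individual PF and FPF emission rates (count / sessions played).

    Individuals with zero sessions get rate 0 under ``zero_convention="zero"``
    (the default, which keeps the full group in group-level means) and are
    dropped under ``"exclude"``.
    """
    if zero_convention not in ("zero", "exclude"):
        raise ValueError("zero_convention must be 'zero' or 'exclude'")
    rows = []
    for s in summaries:
        if s.n_sessions == 0:
            if zero_convention == "exclude":
                continue
            pf_rate = fpf_rate = 0.0
        else:
            pf_rate = s.n_pf / s.n_sessions
            fpf_rate = s.n_fpf / s.n_sessions
        rows.append({"individual": s.individual, "group": s.group,
                     "n_sessions": s.n_sessions, "pf_rate": pf_rate,
                     "fpf_rate": fpf_rate})
    return pd.DataFrame(rows)
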