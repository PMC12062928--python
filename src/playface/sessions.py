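"""Session-level condition classification and timing metrics.

For the session-duration analysis each play session falls into exactly one
of six labels:

* ``PF_RFM`` / ``FPF_RFM`` — at least one mimicry event of that expression
  type (and none of the other) occurred;
* ``PF_and_FPF_RFM`` — mimicry of both types occurred in the same session;
* ``PF_not_mim`` / ``FPF_not_mim`` — no mimicry at all, and at least two
  unreplicated expressions of one type with none of the other type;
* ``excluded`` — no expressions, too few of them, or an ambiguous mix of
  unreplicated PF and FPF.

``time_remaining`` measures, per classified session, the seconds from the
first qualifying event (first unreplicated expression for the not-mim
conditions, first mimicry stimulus for the RFM conditions) to the session
end; comparing it across conditions asks whether mimicry prolongs play.
``midpoint_flag`` records whether the first mimicry event fell in the first
half of the session (1) or not (0).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .ethogram import PlaySession
from .rfm import StimulusRecord

__all__ = [
    "CONDITION_LABELS",
    "SessionCondition",
    "classify_condition",
    "time_remaining",
    "midpoint_flag",
    "condition_table",
]

CONDITION_LABELS = ("PF_not_mim", "FPF_not_mim", "PF_RFM", "FPF_RFM",
                    "PF_and_FPF_RFM", "excluded")


@dataclass(frozen=True)
class SessionCondition:
    label: str
    first_event_time: Optional[float] = None

    def __post_init__(self):
        if self.label not in CONDITION_LABELS:
            raise ValueError(f"unknown condition label {self.label!r}")


def classify_condition(session: PlaySession,
                       rfm_records: Sequence[StimulusRecord]) -> SessionCondition:
    """Assign the session its condition label.

    Priority: both mimicry types > one mimicry type > at-least-two
    unreplicated expressions of a single type. Mixed unreplicated PF and
    FPF, fewer than two expressions, or no expressions at all are excluded.
    """
    recs = [r for r in rfm_records if r.session_id == session.session_id]
    rep_pf = sorted(r.onset for r in recs if r.replicated and r.expr_type == "PF")
    rep_fpf = sorted(r.onset for r in recs if r.replicated and r.expr_type == "FPF")
    if rep_pf and rep_fpf:
        return SessionCondition("PF_and_FPF_RFM", min(rep_pf[0], rep_fpf[0]))
    if rep_fpf:
        return SessionCondition("FPF_RFM", rep_fpf[0])
    if rep_pf:
        return SessionCondition("PF_RFM", rep_pf[0])
    # no mimicry: every expression in the session is unreplicated
    pf = sorted(r.onset for r in recs if r.expr_type == "PF")
    fpf = sorted(r.onset for r in recs if r.expr_type == "FPF")
    if len(pf) >= 2 and not fpf:
        return SessionCondition("PF_not_mim", pf[0])
    if len(fpf) >= 2 and not pf:
        return SessionCondition("FPF_not_mim", fpf[0])
    return SessionCondition("excluded")


def time_remaining(session: PlaySession,
                   condition: SessionCondition) -> float:
    """Seconds between the condition's first qualifying event and session
    end. NaN for excluded sessions."""
    if condition.label == "excluded" or condition.first_event_time is None:
        return float("nan")
    return session.end - condition.first_event_time


def midpoint_flag(session: PlaySession,
                  rfm_records: Sequence[StimulusRecord]) -> Optional[int]:
    """1 when the first mimicry stimulus falls strictly before the session
    midpoint, 0 otherwise (ties count as after); None without mimicry."""
    onsets = [r.onset for r in rfm_records
              if r.session_id == session.session_id and r.replicated]
    if not onsets:
        return None
    midpoint = session.start + session.duration / 2.0
    return 1 if min(onsets) < midpoint else 0


def condition_table(sessions: Sequence[PlaySession],
                    records: Sequence[StimulusRecord]) -> pd.DataFrame:
    """Per-session condition, first event time, time remaining and midpoint
    flag, ready for TSV export."""
    rows = []
    for s in sessions:
        cond = classify_condition(s, records)
        rows.append({
            "session_id": s.session_id,
            "condition": cond.label,
            "first_event_time": cond.first_event_time,
            "time_remaining": time_remaining(s, cond),
            "midpoint_flag": midpoint_flag(s, records),
        })
    return pd.DataFrame(rows, columns=["session_id", "condition",
                                       "first_event_time", "time_remaining",
                                       "midpoint_flag"])
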