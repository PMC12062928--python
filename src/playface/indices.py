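"""Play Asymmetry Index, Shannon diversity of play patterns, and the
sequential before/after windowing around expressions and mimicry events.

PAI quantifies the offense/defense imbalance between the two players of a
window: directed offensive acts by A plus defensive acts by B, minus the
mirror counts, over *all* patterns in the window (offensive + defensive +
neutral, solitary patterns included in the denominator only). It ranges
from -1 (asymmetry in favor of B) to +1 (in favor of A).

H' is the natural-log Shannon index over pattern *types* (pattern names,
not categories): H' = -sum(n_i/N * ln(n_i/N)). Higher values mean more
varied play.

The sequential analysis takes, for each focal event (an expression or the
stimulus of a mimicry event), the k patterns strictly before and strictly
after its onset, and computes both indices on each side. Focal events too
close together are thinned so the windows of retained events never overlap
and are separated by a minimum run of unused patterns.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

from .ethogram import PatternEvent, PlaySession

__all__ = [
    "WindowPair",
    "IndexPair",
    "pai",
    "shannon",
    "extract_windows",
    "before_after_indices",
]


def _onset(event) -> float:
    """Focal position of an event: expression onset, or the stimulus onset
    for a mimicry record."""
    return event.onset


@dataclass(frozen=True)
class WindowPair:
    """The patterns flanking one focal event."""

    focal: object
    before: tuple[PatternEvent, ...]
    after: tuple[PatternEvent, ...]
    k: int

    def __post_init__(self):
        if len(self.before) > self.k or len(self.after) > self.k:
            raise ValueError("window side exceeds k")


@dataclass(frozen=True)
class IndexPair:
    pai_before: float
    pai_after: float
    h_before: float
    h_after: float


def pai(patterns: Sequence[PatternEvent], player_a: str, player_b: str) -> float:
    """Play Asymmetry Index of a pattern window, oriented toward player_a.

    Numerator: offensive A->B plus defensive B->A, minus offensive B->A plus
    defensive A->B. Denominator: every pattern in the window regardless of
    category, direction or solitariness. NaN on an empty window. Swapping
    the player arguments negates the value.
    """
    if player_a == player_b:
        raise ValueError("players must be distinct")
    if not patterns:
        return float("nan")
    num = 0
    for ev in patterns:
        if ev.target is None:
            continue  # solitary: denominator only
        if ev.category == "offensive":
            num += 1 if ev.actor == player_a else -1
        elif ev.category == "defensive":
            num += 1 if ev.actor == player_b else -1
    return num / len(patterns)


def shannon(patterns: Sequence[PatternEvent]) -> float:
    """Natural-log Shannon diversity over pattern names. NaN on empty input."""
    if not patterns:
        return float("nan")
    counts = Counter(ev.pattern for ev in patterns)
    n = len(patterns)
    return -sum((c / n) * math.log(c / n) for c in counts.values())


def extract_windows(session: PlaySession, focal_events: Sequence,
                    k: int = 4, min_separation: int = 4) -> list[WindowPair]:
    """Select the k patterns before and after each focal event.

    Focal events must be time-sorted. Consecutive focal events are both
    retained only when at least ``2*k + min_separation`` patterns lie
    strictly between their onsets, so the two windows never share patterns
    and a buffer of ``min_separation`` unused patterns separates them;
    otherwise the later event is excluded, and the spacing check continues
    from the last *retained* event. An event with fewer than k patterns on a
    side keeps a short window if the side has at least one pattern; an event
    with an empty side is dropped (and does not count for spacing).
    """
    patterns = session.pattern_events  # already time-sorted
    times = [p.time for p in patterns]
    required = 2 * k + min_separation
    out: list[WindowPair] = []
    last_retained_onset: Optional[float] = None
    for ev in focal_events:
        t = _onset(ev)
        if last_retained_onset is not None:
            between = sum(1 for x in times if last_retained_onset < x < t)
            if between < required:
                continue
        before = tuple(p for p in patterns if p.time < t)[-k:]
        after = tuple(p for p in patterns if p.time > t)[:k]
        if not before or not after:
            continue
        out.append(WindowPair(focal=ev, before=before, after=after, k=k))
        last_retained_onset = t
    return out


def before_after_indices(window: WindowPair,
                         players: tuple[str, str]) -> IndexPair:
    """PAI and H' on both sides of a focal event, PAI oriented toward
    ``players[0]``."""
    a, b = players
    return IndexPair(
        pai_before=pai(list(window.before), a, b),
        pai_after=pai(list(window.after), a, b),
        h_before=shannon(list(window.before)),
        h_after=shannon(list(window.after)),
    )
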