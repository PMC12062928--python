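"""Synthetic dyadic play sessions with known ground truth.

The generator emulates the statistical structure the analyses assume, so
every pipeline stage can be exercised end-to-end without observational
data: sessions are built pattern by pattern at irregular (exponential)
inter-event gaps; each pattern draws an actor, a category (offensive /
defensive / neutral) and a pattern name from session-specific
Dirichlet-weighted distributions; PF/FPF expressions arise at a fixed
per-player rate, are perceived or not by the partner, and are congruently
replicated within one second with a perception-dependent probability.

Three ground-truth effects can be injected, each mirroring a phenomenon
the pipeline is meant to detect:

* after the first mimicry event the per-pattern termination hazard is
  multiplied by ``hazard_multiplier_post_rfm`` (< 1 prolongs the session);
* for ``effect_window_patterns`` patterns after an *unreplicated FPF* the
  offensive-category probability is shifted up by ``offense_bias_post_fpf``
  and offense is directed by the emitter (raising the asymmetry index in
  the post window);
* for the same span after an *unreplicated PF* pattern choice is mixed
  toward the uniform distribution with weight ``diversity_boost_post_pf``
  (raising the Shannon index in the post window).

Identical parameters (including the seed) give byte-identical event logs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .ethogram import (ExpressionEvent, PatternEvent, PlaySession,
                       packaged_ethogram)

__all__ = ["GeneratorParams", "GroundTruth", "generate", "null_params",
           "effects_params"]

# neutral patterns a gorilla can perform alone (no target)
SOLITARY_PATTERNS = frozenset({
    "pirouetting", "somersault", "acrobatic play", "play jump (alone)",
    "play roll", "play turn around", "play manipulation", "play slide down",
})

# expressions are modeled separately, not as patterns
_NON_PATTERNS = frozenset({"play face", "full play face"})


@dataclass(frozen=True)
class GeneratorParams:
    """Knobs of the synthetic play-session generator.

    Defaults encode the observed study conditions where the source numbers
    allow it: mean session length about 43 s (hazard 0.05 per pattern at a
    2 s mean gap), roughly one expression per session per dyad
    (0.8 per player-minute), 72% of expressions being FPF, 75% of stimuli
    perceived, and replication probabilities 0.59 (perceived) versus 0.20
    (not perceived) taken from the aggregate perception-by-replication
    counts. The three effect sizes default to a clearly detectable regime
    (hazard multiplier 0.4, offense shift 0.3, diversity boost 0.7).
    """

    n_dyads: int = 10
    sessions_per_dyad: int = 10
    mean_gap_s: float = 2.0
    category_weights: tuple[float, float, float] = (0.45, 0.15, 0.40)
    p_offense_by_initiator: float = 0.65
    expression_rate_per_min: float = 0.8
    expression_rate_dispersion: float = 0.5
    fpf_fraction: float = 0.72
    type_persistence: float = 0.7
    p_perceived: float = 0.75
    p_replicate_yes: float = 0.59
    p_replicate_no: float = 0.20
    response_window_s: float = 1.0
    baseline_hazard: float = 0.05
    hazard_multiplier_post_rfm: float = 0.4
    offense_bias_post_fpf: float = 0.3
    diversity_boost_post_pf: float = 0.7
    effect_window_patterns: int = 4
    pattern_concentration: float = 0.12
    category_concentration: float = 1.5
    pattern_repeat: float = 0.4
    expression_duration_range: tuple[float, float] = (0.5, 4.0)
    max_patterns_per_session: int = 200
    seed: int = 0

    def validate(self) -> None:
        probs = (self.p_offense_by_initiator, self.fpf_fraction,
                 self.p_perceived, self.p_replicate_yes, self.p_replicate_no,
                 self.offense_bias_post_fpf, self.diversity_boost_post_pf,
                 self.type_persistence, self.pattern_repeat)
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if min(self.category_weights) < 0 or sum(self.category_weights) <= 0:
            raise ValueError("category weights must be non-negative, not all zero")
        if self.mean_gap_s <= 0 or self.baseline_hazard <= 0:
            raise ValueError("mean gap and hazard must be positive")
        if self.hazard_multiplier_post_rfm <= 0:
            raise ValueError("hazard multiplier must be positive")
        if self.pattern_concentration <= 0 or self.category_concentration <= 0:
            raise ValueError("Dirichlet concentrations must be positive")
        if self.n_dyads < 1 or self.sessions_per_dyad < 1:
            raise ValueError("need at least one dyad and one session")
        if self.expression_rate_per_min < 0:
            raise ValueError("expression rate must be non-negative")
        if self.expression_rate_dispersion < 0:
            raise ValueError("expression rate dispersion must be non-negative")


@dataclass
class GroundTruth:
    """What the generator actually drew, aligned with the emitted log."""

    params: GeneratorParams
    stimuli: pd.DataFrame  # one row per generated expression stimulus
    session_labels: dict[str, str] = field(default_factory=dict)


def null_params(seed: int = 0, **overrides) -> GeneratorParams:
    """Parameters with every effect switched off: equal replication
    probability in both perception conditions, no hazard change after
    mimicry, no offense shift, no diversity boost. The baseline for
    type-I-error suites."""
    base = GeneratorParams(seed=seed,
                           p_replicate_yes=0.3, p_replicate_no=0.3,
                           hazard_multiplier_post_rfm=1.0,
                           offense_bias_post_fpf=0.0,
                           diversity_boost_post_pf=0.0)
    return replace(base, **overrides)


def effects_params(seed: int = 0, **overrides) -> GeneratorParams:
    """The default effects-on regime (alias for the dataclass defaults)."""
    return replace(GeneratorParams(seed=seed), **overrides)


def _pattern_pools():
    eth = packaged_ethogram()
    pools: dict[str, list[str]] = {"offensive": [], "defensive": [], "neutral": []}
    for pat, cat in sorted(eth.entries.items()):
        if pat in _NON_PATTERNS:
            continue
        pools[cat].append(pat)
    return eth, pools


def generate(params: GeneratorParams) -> tuple[list[PlaySession], GroundTruth]:
    """Simulate the configured number of sessions.

    Returns the sessions plus a :class:`GroundTruth` holding the raw
    stimulus draws (perception and replication as *generated*, before any
    detection step) and the per-session condition labels implied by them.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    eth, pools = _pattern_pools()
    cat_names = ("offensive", "defensive", "neutral")
    base_w = np.asarray(params.category_weights, dtype=float)
    base_w = base_w / base_w.sum()
    delta = params.offense_bias_post_fpf
    k_eff = params.effect_window_patterns
    dur_lo, dur_hi = params.expression_duration_range

    sessions: list[PlaySession] = []
    truth_rows: list[dict] = []
    labels: dict[str, str] = {}

    for di in range(params.n_dyads):
        a, b = f"d{di:02d}x", f"d{di:02d}y"
        group = "VDS" if di % 2 else "BEA"
        for si in range(params.sessions_per_dyad):
            sid = f"s{di:02d}_{si:03d}"
            # session-specific concentrated pattern distributions; the
            # category mix itself also varies across sessions, so short
            # windows show the low pattern diversity seen in real play
            pat_probs = {c: rng.dirichlet(np.full(len(pools[c]),
                                                  params.pattern_concentration))
                         for c in cat_names}
            sess_w = rng.dirichlet(base_w * 3 * params.category_concentration)
            # sessions differ in expressiveness: a unit-mean gamma multiplier
            # concentrates expressions in a minority of sessions
            k_disp = params.expression_rate_dispersion
            rate_mult = rng.gamma(k_disp, 1.0 / k_disp) if k_disp > 0 else 1.0
            initiator = a if rng.random() < 0.5 else b
            other = b if initiator == a else a
            patterns: list[PatternEvent] = []
            expressions: list[ExpressionEvent] = []
            t = 0.0
            rfm_occurred = False
            last_expr_type = None
            last_pattern = None  # (pattern, category) of the previous step
            # partner replication is modeled only through p_replicate, so a
            # player's *independent* emissions are suppressed while they are
            # inside the response window of the partner's latest expression
            suppress_until = {a: -1.0, b: -1.0}
            offense_left = 0
            offense_player = initiator
            boost_left = 0
            rep_types: set[str] = set()
            unrep_counts = {"PF": 0, "FPF": 0}

            while len(patterns) < params.max_patterns_per_session:
                gap = rng.exponential(params.mean_gap_s)
                t += gap
                boosting = boost_left > 0 and rng.random() < params.diversity_boost_post_pf
                # play comes in bouts: outside a diversity-boost window the
                # previous pattern may simply repeat
                repeat = (not boosting and last_pattern is not None
                          and rng.random() < params.pattern_repeat)
                if repeat:
                    pat, cat = last_pattern
                else:
                    # category, with the post-FPF offense shift when active
                    w = sess_w.copy()
                    if offense_left > 0 and delta > 0:
                        w[0] = w[0] + delta * (1 - w[0])
                        rest = w[1] + w[2]
                        if rest > 0:
                            w[1:] *= (1 - w[0]) / rest
                    cat = cat_names[rng.choice(3, p=w)]
                if cat == "offensive":
                    if offense_left > 0 and delta > 0:
                        actor = offense_player
                    else:
                        actor = initiator if rng.random() < params.p_offense_by_initiator else other
                elif cat == "defensive":
                    actor = other if rng.random() < params.p_offense_by_initiator else initiator
                else:
                    actor = initiator if rng.random() < 0.5 else other
                if not repeat:
                    pool = pools[cat]
                    if boosting:
                        pat = pool[rng.integers(len(pool))]
                    else:
                        pat = pool[rng.choice(len(pool), p=pat_probs[cat])]
                last_pattern = (pat, cat)
                target = None if pat in SOLITARY_PATTERNS else (
                    b if actor == a else a)
                patterns.append(PatternEvent(time=t, actor=actor, target=target,
                                             pattern=pat, category=cat))
                offense_left = max(0, offense_left - 1)
                boost_left = max(0, boost_left - 1)

                # expression emissions tied to this step's time interval
                p_expr = min(1.0, rate_mult * params.expression_rate_per_min
                             / 60.0 * gap)
                for emitter in (a, b):
                    if rng.random() >= p_expr:
                        continue
                    onset = t + 0.02 + 0.1 * rng.random()
                    if onset <= suppress_until[emitter]:
                        continue
                    # within a session expression types are sticky: sessions
                    # with only one type occur at realistic frequency
                    if (last_expr_type is not None
                            and rng.random() < params.type_persistence):
                        expr = last_expr_type
                    else:
                        expr = "FPF" if rng.random() < params.fpf_fraction else "PF"
                    last_expr_type = expr
                    perceived = rng.random() < params.p_perceived
                    annotation = (("frontal" if rng.random() < 0.5 else "lateral")
                                  if perceived else "blind")
                    p_rep = (params.p_replicate_yes if perceived
                             else params.p_replicate_no)
                    replicated = rng.random() < p_rep
                    duration = rng.uniform(dur_lo, dur_hi)
                    expressions.append(ExpressionEvent(
                        onset=onset, offset=onset + duration, emitter=emitter,
                        expr_type=expr, partner_perception=annotation))
                    partner = b if emitter == a else a
                    suppress_until[partner] = max(suppress_until[partner],
                                                  onset + params.response_window_s)
                    latency = np.nan
                    if replicated:
                        latency = params.response_window_s * (1 - rng.random())
                        r_onset = onset + latency
                        r_dur = rng.uniform(dur_lo, dur_hi)
                        expressions.append(ExpressionEvent(
                            onset=r_onset, offset=r_onset + r_dur,
                            emitter=partner, expr_type=expr,
                            partner_perception="frontal"))
                        rfm_occurred = True
                        rep_types.add(expr)
                    else:
                        unrep_counts[expr] += 1
                        if expr == "FPF":
                            offense_left = k_eff
                            offense_player = emitter
                        else:
                            boost_left = k_eff
                    truth_rows.append({
                        "session_id": sid, "dyad": f"d{di:02d}",
                        "group": group, "trigger": emitter,
                        "expr_type": expr, "onset": onset,
                        "perceived": perceived, "replicated": replicated,
                        "latency": latency})

                hazard = params.baseline_hazard * (
                    params.hazard_multiplier_post_rfm if rfm_occurred else 1.0)
                if rng.random() < min(1.0, hazard):
                    break

            end = max([p.time for p in patterns]
                      + [e.offset for e in expressions])
            sessions.append(PlaySession(
                session_id=sid, group_id=group, player_a=a, player_b=b,
                start=0.0, end=end, pattern_events=patterns,
                expression_events=expressions))
            labels[sid] = _label(rep_types, unrep_counts)

    cols = ["session_id", "dyad", "group", "trigger", "expr_type", "onset",
            "perceived", "replicated", "latency"]
    truth = GroundTruth(params=params,
                        stimuli=pd.DataFrame(truth_rows, columns=cols),
                        session_labels=labels)
    return sessions, truth


def _label(rep_types: set[str], unrep: dict[str, int]) -> str:
    if rep_types == {"PF", "FPF"}:
        return "PF_and_FPF_RFM"
    if rep_types == {"FPF"}:
        return "FPF_RFM"
    if rep_types == {"PF"}:
        return "PF_RFM"
    if unrep["PF"] >= 2 and unrep["FPF"] == 0:
        return "PF_not_mim"
    if unrep["FPF"] >= 2 and unrep["PF"] == 0:
        return "FPF_not_mim"
    return "excluded"
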