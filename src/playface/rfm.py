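"""Rapid Facial Mimicry (RFM) detection and perception-condition analysis.

RFM is the involuntary, congruent replication of a perceived facial
expression within one second of its emission: a PF answered by a PF, an FPF
by an FPF (exact facial matching). Each expression emitted by a player (the
*trigger*) is treated as a stimulus toward the partner (the *potential
responder*); the stimulus is *replicated* when the partner emits an
expression of the same type with onset within the response window.

The distinction between mimicry and mere synchrony rests on the perception
condition: a stimulus falling in the responder's frontal or lateral visual
field counts as perceived, one falling in the blind area as not perceived,
and doubtful annotations are discarded. Perception-by-replication counts go
into 2x2 contingency tables and into the design table for a binomial
mixed model with trigger-responder dyad as random intercept.
"""

from __future__ import annotations

import json
import subprocess
import tempfile
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .ethogram import ExpressionEvent, PlaySession

__all__ = [
    "StimulusRecord",
    "Contingency2x2",
    "classify_perception",
    "detect_rfm",
    "build_contingency",
    "rfm_level",
    "glmm_design_table",
    "write_design_table",
    "fit_binomial_glmm",
]


@dataclass(frozen=True)
class StimulusRecord:
    """One expression treated as a stimulus toward the play partner."""

    session_id: str
    trigger: str
    responder: str
    expr_type: str
    onset: float
    perception: str  # yes / no / unknown
    replicated: bool
    latency: Optional[float] = None
    group_id: Optional[str] = None

    def __post_init__(self):
        if self.replicated and self.latency is None:
            raise ValueError("replicated stimulus must carry a latency")

    @property
    def dyad_id(self) -> str:
        return f"{self.trigger}|{self.responder}"


@dataclass(frozen=True)
class Contingency2x2:
    """Counts of (perceived, replicated) combinations for one expression
    type: a = perceived & replicated, b = perceived & not, c = not perceived
    & replicated, d = not perceived & not."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self):
        return [[self.a, self.b], [self.c, self.d]]


def classify_perception(event: ExpressionEvent) -> str:
    """Map the partner-perception annotation to the analysis condition:
    frontal or lateral view -> "yes", blind area -> "no", doubtful ->
    "unknown" (discarded downstream)."""
    return {"frontal": "yes", "lateral": "yes", "blind": "no",
            "unknown": "unknown"}[event.partner_perception]


def detect_rfm(session: PlaySession, window_s: float = 1.0) -> list[StimulusRecord]:
    """Scan one session for rapid congruent replication of expressions.

    Every expression is a potential stimulus unless it was itself consumed
    as the response to an earlier stimulus. A stimulus is replicated when
    the partner emits an expression of the *same* type with onset strictly
    after the stimulus onset and at most ``window_s`` later (onset-to-onset
    latency, boundary inclusive). Pairing is greedy earliest-first and each
    expression can answer at most one stimulus.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    events = sorted(session.expression_events, key=lambda e: e.onset)
    consumed: set[int] = set()  # indices used as responses
    records: list[StimulusRecord] = []
    for i, ev in enumerate(events):
        if i in consumed:
            continue
        partner = session.partner_of(ev.emitter)
        response_idx = None
        for j in range(i + 1, len(events)):
            cand = events[j]
            if cand.onset - ev.onset > window_s:
                break
            if (j not in consumed and cand.emitter == partner
                    and cand.expr_type == ev.expr_type and cand.onset > ev.onset):
                response_idx = j
                break
        latency = None
        if response_idx is not None:
            consumed.add(response_idx)
            latency = events[response_idx].onset - ev.onset
        records.append(StimulusRecord(
            session_id=session.session_id, trigger=ev.emitter,
            responder=partner, expr_type=ev.expr_type, onset=ev.onset,
            perception=classify_perception(ev),
            replicated=response_idx is not None, latency=latency,
            group_id=session.group_id))
    return records


def build_contingency(records: Iterable[StimulusRecord],
                      expr_type: str) -> Contingency2x2:
    """Perception-by-replication counts for one expression type.

    Records with unknown perception are dropped; the four cells partition
    the remaining stimuli.
    """
    recs = [r for r in records if r.expr_type == expr_type and r.perception != "unknown"]
    if not recs:
        warnings.warn(f"no {expr_type} stimuli with known perception; "
                      "returning an all-zero table")
    a = sum(1 for r in recs if r.perception == "yes" and r.replicated)
    b = sum(1 for r in recs if r.perception == "yes" and not r.replicated)
    c = sum(1 for r in recs if r.perception == "no" and r.replicated)
    d = sum(1 for r in recs if r.perception == "no" and not r.replicated)
    return Contingency2x2(a, b, c, d)


def rfm_level(records: Iterable[StimulusRecord], individual: str,
              expr_type: Optional[str] = None) -> float:
    """An individual's mimicry level: expressions they replicated divided by
    expressions they perceived. NaN when they perceived none (such
    individuals are excluded from level comparisons)."""
    perceived = [r for r in records
                 if r.responder == individual and r.perception == "yes"
                 and (expr_type is None or r.expr_type == expr_type)]
    if not perceived:
        return float("nan")
    return sum(r.replicated for r in perceived) / len(perceived)


def glmm_design_table(records: Iterable[StimulusRecord],
                      group_codes: Optional[dict] = None) -> pd.DataFrame:
    """One row per known-perception stimulus, coded for a binomial mixed
    model: response (0/1 replication), perception (0 = no, 1 = yes), group
    (integer code), dyad_id (random-intercept factor).

    The table is the full input contract for an external binomial GLMM with
    dyad random intercept; the accompanying likelihood-ratio comparison is
    full model (perception + group + dyad intercept) versus null (dyad
    intercept only). ``group_codes`` maps group ids to integers; by default
    groups are numbered 1, 2, ... in sorted order.
    """
    recs = [r for r in records if r.perception != "unknown"]
    if group_codes is None:
        groups = sorted({r.group_id for r in recs if r.group_id is not None})
        group_codes = {g: i + 1 for i, g in enumerate(groups)}
    rows = [{"response": int(r.replicated),
             "perception": int(r.perception == "yes"),
             "group": group_codes.get(r.group_id, 0),
             "dyad_id": r.dyad_id}
            for r in recs]
    return pd.DataFrame(rows, columns=["response", "perception", "group", "dyad_id"])


def write_design_table(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t", index=False)


_R_GLMM = """
suppressMessages(library(lme4))
suppressMessages(library(jsonlite))
d <- read.delim(commandArgs(trailingOnly = TRUE)[1])
d$dyad_id <- factor(d$dyad_id)
use_group <- length(unique(d$group)) > 1
form <- if (use_group) response ~ perception + factor(group) + (1 | dyad_id) else
  response ~ perception + (1 | dyad_id)
full <- glmer(form, family = binomial, data = d,
              control = glmerControl(check.conv.singular = "ignore"))
null <- glmer(response ~ (1 | dyad_id), family = binomial, data = d,
              control = glmerControl(check.conv.singular = "ignore"))
a <- anova(null, full)
s <- summary(full)$coefficients
out <- list(coefficients = as.list(s[, "Estimate"]),
            se = as.list(s[, "Std. Error"]),
            p_values = as.list(s[, "Pr(>|z|)"]),
            lrt_chi2 = a$Chisq[2], lrt_df = a$Df[2], lrt_p = a$`Pr(>Chisq)`[2])
cat(toJSON(out, auto_unbox = TRUE, digits = 10))
"""


def fit_binomial_glmm(design: pd.DataFrame, timeout: float = 300.0) -> dict:
    """Fit the binomial mixed model on a design table via lme4 (Rscript).

    Returns fixed-effect estimates/SEs/p-values keyed by term name plus the
    full-versus-null likelihood-ratio test (``lrt_chi2``, ``lrt_df``,
    ``lrt_p``). Model estimation itself is delegated to lme4's ``glmer``;
    this package only builds the design table and defines the comparison.
    """
    if design.empty:
        raise ValueError("empty design table")
    with tempfile.TemporaryDirectory() as tmp:
        data = Path(tmp) / "design.tsv"
        script = Path(tmp) / "fit.R"
        write_design_table(design, data)
        script.write_text(_R_GLMM)
        proc = subprocess.run(
            ["Rscript", "--vanilla", str(script), str(data)],
            capture_output=True, text=True, timeout=timeout)
    if proc.returncode != 0:
        raise RuntimeError(f"lme4 fit failed:\n{proc.stderr}")
    payload = proc.stdout.strip().splitlines()[-1]
    return json.loads(payload)
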