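"""End-to-end analysis drivers combining detection, indices and tests.

These functions assemble the four analyses the package exists for:

* mimicry occurrence — perception-by-replication contingency tables per
  expression type with Yates chi-square, plus the GLMM design tables;
* sequential analysis — asymmetry (PAI) and diversity (H') before versus
  after each focal event, with a Wilcoxon test per focal kind;
* session durations — time remaining from the first qualifying event
  across the five session conditions (Kruskal-Wallis with Monte Carlo
  randomization, Dunn-Bonferroni post hocs) and the midpoint binomial test;
* expression rates — per-individual PF/FPF rates with the paired t-test.
"""

from __future__ import annotations

from typing import Optional, Sequence

import pandas as pd

from . import rfm as rfm_mod
from .ethogram import IndividualSummary, PlaySession, rates_per_session
from .indices import before_after_indices, extract_windows
from .rfm import StimulusRecord, build_contingency, glmm_design_table
from .sessions import CONDITION_LABELS, condition_table
from .stats import (TestResult, binomial_exact, dunn_bonferroni,
                    kruskal_wallis_mc, paired_t, wilcoxon_exact, yates_chi2)

__all__ = [
    "detect_all_rfm",
    "rfm_analysis",
    "sequential_table",
    "sequential_tests",
    "durations_analysis",
    "rates_analysis",
]


def detect_all_rfm(sessions: Sequence[PlaySession],
                   window_s: float = 1.0) -> list[StimulusRecord]:
    records: list[StimulusRecord] = []
    for s in sessions:
        records.extend(rfm_mod.detect_rfm(s, window_s=window_s))
    return records


def rfm_analysis(sessions: Sequence[PlaySession],
                 window_s: float = 1.0) -> dict:
    """Contingency tables, chi-square tests and GLMM design tables for both
    expression types."""
    records = detect_all_rfm(sessions, window_s=window_s)
    out = {"records": records, "contingency": {}, "chi2": {}, "design": {}}
    for expr in ("PF", "FPF"):
        table = build_contingency(records, expr)
        out["contingency"][expr] = table
        out["chi2"][expr] = (yates_chi2(table) if table.total else None)
        out["design"][expr] = glmm_design_table(
            [r for r in records if r.expr_type == expr])
    return out


def _focal_kind(record: StimulusRecord) -> str:
    if record.replicated:
        return f"{record.expr_type}_RFM"
    return f"{record.expr_type}-not-mim"


def sequential_table(sessions: Sequence[PlaySession],
                     records: Optional[Sequence[StimulusRecord]] = None,
                     k: int = 4, min_separation: int = 4,
                     window_s: float = 1.0,
                     orientation: str = "emitter") -> pd.DataFrame:
    """Before/after PAI and H' for every retained focal event.

    Focal events are the stimulus records of a session (unreplicated
    expressions and mimicry stimuli alike), thinned by the spacing rule.
    PAI orientation is configurable: ``"emitter"`` points player A at the
    focal event's trigger (so a positive shift means asymmetry moved toward
    the signaler), ``"initiator"`` keeps the session's player order.
    """
    if orientation not in ("emitter", "initiator"):
        raise ValueError("orientation must be 'emitter' or 'initiator'")
    if records is None:
        records = detect_all_rfm(sessions, window_s=window_s)
    by_session: dict[str, list[StimulusRecord]] = {}
    for r in records:
        by_session.setdefault(r.session_id, []).append(r)
    rows = []
    for s in sessions:
        focals = sorted(by_session.get(s.session_id, []), key=lambda r: r.onset)
        for w in extract_windows(s, focals, k=k, min_separation=min_separation):
            rec: StimulusRecord = w.focal
            if orientation == "emitter":
                players = (rec.trigger, rec.responder)
            else:
                players = (s.player_a, s.player_b)
            idx = before_after_indices(w, players)
            rows.append({"session_id": s.session_id,
                         "focal_kind": _focal_kind(rec),
                         "pai_before": idx.pai_before,
                         "pai_after": idx.pai_after,
                         "h_before": idx.h_before,
                         "h_after": idx.h_after})
    return pd.DataFrame(rows, columns=["session_id", "focal_kind",
                                       "pai_before", "pai_after",
                                       "h_before", "h_after"])


def sequential_tests(table: pd.DataFrame) -> dict[str, dict[str, TestResult]]:
    """Per focal kind, the paired Wilcoxon of after versus before values of
    each index (skipping kinds with fewer than two events)."""
    out: dict[str, dict[str, TestResult]] = {}
    for kind, grp in table.groupby("focal_kind"):
        if len(grp) < 2:
            continue
        out[kind] = {
            "pai": wilcoxon_exact(grp["pai_after"].to_numpy(),
                                  grp["pai_before"].to_numpy()),
            "h": wilcoxon_exact(grp["h_after"].to_numpy(),
                                grp["h_before"].to_numpy()),
        }
    return out


def durations_analysis(sessions: Sequence[PlaySession],
                       records: Optional[Sequence[StimulusRecord]] = None,
                       n_perm: int = 10000, seed: Optional[int] = None,
                       window_s: float = 1.0) -> dict:
    """Five-condition comparison of time remaining plus the midpoint test."""
    if records is None:
        records = detect_all_rfm(sessions, window_s=window_s)
    table = condition_table(sessions, records)
    kept = table[table["condition"] != "excluded"]
    groups, labels = [], []
    for label in CONDITION_LABELS[:-1]:
        vals = kept.loc[kept["condition"] == label, "time_remaining"].dropna()
        if len(vals):
            groups.append(vals.to_numpy())
            labels.append(label)
    kw = posthoc = None
    if len(groups) >= 2:
        kw = kruskal_wallis_mc(groups, n_perm=n_perm, seed=seed)
        posthoc = dunn_bonferroni(groups, labels=labels)
    flags = table["midpoint_flag"].dropna()
    midpoint = (binomial_exact(int(flags.sum()), int(len(flags)))
                if len(flags) else None)
    return {"table": table, "kw": kw, "posthoc": posthoc,
            "midpoint_binomial": midpoint, "group_labels": labels}


def rates_analysis(summaries: Sequence[IndividualSummary],
                   zero_convention: str = "zero") -> dict:
    """Per-individual PF/FPF rates and the paired comparison of the two."""
    rates = rates_per_session(summaries, zero_convention=zero_convention)
    result = paired_t(rates["pf_rate"].to_numpy(), rates["fpf_rate"].to_numpy())
    return {"rates": rates, "t_test": result,
            "mean_pf_rate": float(rates["pf_rate"].mean()),
            "mean_fpf_rate": float(rates["fpf_rate"].mean())}
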