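"""Facial action-unit (AU) analysis for PF versus FPF.

Two complementary inputs are supported. FACS-style *configurations* are
binary: for each coded expression, the set of AUs whose contraction was
observed (e.g. AU12 lip-corner puller, AU10 upper-lip raiser, AU25 lips
part, AU27 mouth stretch). OpenFace-style *intensity tables* are per-frame
CSV output with one ``AUxx_r`` column per estimated AU on a continuous 0-5
scale; OpenFace estimates intensities for 17 AUs and does not cover AU16 or
AU27.

The comparison of interest is whether PF and FPF recruit different AUs:
which AUs are (almost) always present in each expression's configurations,
and whether per-AU intensities differ between the two expressions within
individuals (exact Wilcoxon per AU, Bonferroni-corrected family-wise).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .stats import TestResult, wilcoxon_exact

__all__ = [
    "OPENFACE_AUS",
    "AUConfiguration",
    "AUIntensityRecord",
    "read_openface_csv",
    "read_configurations",
    "configuration_summary",
    "compare_intensities",
]

# the 17 AUs whose intensity OpenFace 2.0 estimates
OPENFACE_AUS = ("AU01", "AU02", "AU04", "AU05", "AU06", "AU07", "AU09",
                "AU10", "AU12", "AU14", "AU15", "AU17", "AU20", "AU23",
                "AU25", "AU26", "AU45")

_AGGREGATORS = {"max": np.max, "mean": np.mean, "median": np.median}


@dataclass(frozen=True)
class AUConfiguration:
    """Binary FACS coding of one expression: the set of active AU codes."""

    subject: str
    expr_type: str
    active_aus: frozenset[str]

    def __post_init__(self):
        object.__setattr__(self, "active_aus",
                           frozenset(_norm_au(a) for a in self.active_aus))


@dataclass(frozen=True)
class AUIntensityRecord:
    """Per-clip AU intensities (one value per AU after frame aggregation)."""

    subject: str
    expr_type: str
    clip_id: str
    intensities: dict[str, float]

    def __post_init__(self):
        if any(v < 0 for v in self.intensities.values()):
            raise ValueError("intensities must be non-negative")


def _norm_au(code: str) -> str:
    m = re.fullmatch(r"\s*AU\s*0*(\d+)\s*", str(code), flags=re.IGNORECASE)
    if not m:
        raise ValueError(f"not an AU code: {code!r}")
    return f"AU{int(m.group(1)):02d}"


def read_openface_csv(path, subject: str = "", expr_type: str = "",
                      clip_id: Optional[str] = None,
                      aggregator: str = "max") -> list[AUIntensityRecord]:
    """Read an OpenFace output CSV and aggregate frames to clip level.

    Headers are whitespace-trimmed (OpenFace pads them). Intensity columns
    are those ending in ``_r``. When the file carries ``subject`` /
    ``expr_type`` / ``clip`` columns, rows are grouped by them; otherwise
    the whole file is one clip described by the arguments. The per-AU
    aggregator across frames defaults to the maximum (the apex of the
    expression); ``mean`` and ``median`` are also available.
    """
    if aggregator not in _AGGREGATORS:
        raise ValueError(f"aggregator must be one of {sorted(_AGGREGATORS)}")
    agg = _AGGREGATORS[aggregator]
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty OpenFace file") from None
    df.columns = [c.strip() for c in df.columns]
    au_cols = [c for c in df.columns if re.fullmatch(r"AU\d+_r", c)]
    if not au_cols:
        raise ValueError(f"{path}: no AU intensity (_r) columns found")

    def to_record(sub: str, expr: str, clip: str, frames: pd.DataFrame):
        intensities = {_norm_au(c[:-2]): float(agg(frames[c].to_numpy(dtype=float)))
                       for c in au_cols}
        return AUIntensityRecord(sub, expr, clip, intensities)

    meta = [c for c in ("subject", "expr_type", "clip") if c in df.columns]
    if meta == ["subject", "expr_type", "clip"]:
        return [to_record(str(s), str(e), str(c), g)
                for (s, e, c), g in df.groupby(["subject", "expr_type", "clip"])]
    return [to_record(subject, expr_type, clip_id or "clip0", df)]


def read_configurations(path) -> list[AUConfiguration]:
    """Read a FACS configuration TSV: subject, expr_type, comma-joined AUs."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"subject", "expr_type", "aus"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [AUConfiguration(row["subject"], row["expr_type"],
                            frozenset(a for a in str(row["aus"]).split(",") if a.strip()))
            for _, row in df.iterrows()]


def configuration_summary(configs: Iterable[AUConfiguration], expression: str,
                          threshold: float = 0.8) -> list[tuple[str, float]]:
    """AUs "always or almost always" present in an expression's
    configurations: those whose presence frequency is at least ``threshold``,
    sorted by decreasing frequency (AU code breaks ties)."""
    sel = [c for c in configs if c.expr_type == expression]
    if not sel:
        raise ValueError(f"no configurations for expression {expression!r}")
    all_aus = sorted(set().union(*(c.active_aus for c in sel)))
    freqs = [(au, sum(au in c.active_aus for c in sel) / len(sel)) for au in all_aus]
    out = [(au, f) for au, f in freqs if f >= threshold]
    return sorted(out, key=lambda t: (-t[1], t[0]))


def compare_intensities(records: Sequence[AUIntensityRecord],
                        alpha_family: float = 0.05) -> pd.DataFrame:
    """Within-individual PF-versus-FPF comparison of AU intensities.

    Each subject contributes one value per expression and AU (the median
    across their clips); each AU gets an exact Wilcoxon signed-rank test
    across the subjects that have both expressions. The Bonferroni
    threshold is ``alpha_family / number of AUs tested``; the returned
    frame flags AUs below it and the minimum-p AU, and gives the direction
    of the median difference (positive = stronger during FPF).
    """
    df = pd.DataFrame([
        {"subject": r.subject, "expr_type": r.expr_type, "au": au, "value": v}
        for r in records for au, v in r.intensities.items()])
    if df.empty:
        raise ValueError("no intensity records")
    per_subject = (df.groupby(["subject", "expr_type", "au"])["value"]
                     .median().reset_index())
    wide = per_subject.pivot_table(index=["subject", "au"], columns="expr_type",
                                   values="value").reset_index()
    if not {"PF", "FPF"} <= set(wide.columns):
        raise ValueError("need both PF and FPF records")
    wide = wide.dropna(subset=["PF", "FPF"])
    aus = sorted(wide["au"].unique())
    threshold = alpha_family / len(aus)
    rows = []
    for au in aus:
        sub = wide[wide["au"] == au]
        if len(sub) < 2:
            raise ValueError(f"{au}: fewer than 2 subjects with both expressions")
        res: TestResult = wilcoxon_exact(sub["PF"].to_numpy(), sub["FPF"].to_numpy())
        rows.append({"au": au, "n_subjects": len(sub),
                     "T": res.statistic, "ties": res.ties,
                     "p": res.p_value if res.p_value is not None else np.nan,
                     "direction_fpf_minus_pf": float((sub["FPF"] - sub["PF"]).median())})
    out = pd.DataFrame(rows)
    out["bonferroni_alpha"] = threshold
    out["significant"] = out["p"] < threshold
    finite = out["p"].dropna()
    out["min_p"] = False
    if not finite.empty:
        out.loc[out["p"] == finite.min(), "min_p"] = True
    return out
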