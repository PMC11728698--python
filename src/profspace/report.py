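"""Summary tables, similarity transforms and per-metric tool rankings.

Per-sample metrics are collapsed to medians per (tool, scenario, common
space).  For radar-style comparison every metric is mapped onto a [0, 1]
similarity where higher is better:

* richness and Shannon — Bray–Curtis-style similarity 1 − |u − v|/(u + v)
  between the truth value u and the estimate v (medians per scenario);
* distances to the truth — 1 − d_BC and 1 − d_WUF;
* FPRA — mapped to TPRA = 1 − FPRA;
* sensitivity and precision — already on [0, 1], passed through unchanged.

Rankings are per metric (no composite score); ties share a rank.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .metrics import EvaluationReport, SampleMetrics, _METRIC_FIELDS

__all__ = ["ToolSummary", "summarize", "to_similarities", "rank_report",
           "write_rank_report"]

SIMILARITY_METRICS = (
    "richness", "shannon", "bray_curtis", "unifrac",
    "sensitivity", "precision", "tpra",
)


@dataclass
class ToolSummary:
    tool: str
    scenario: str = ""
    space: str = ""
    medians: dict[str, float] = field(default_factory=dict)
    n_missing: dict[str, int] = field(default_factory=dict)
    n_samples: int = 0
    similarities: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k, v in self.similarities.items():
            if not np.isnan(v) and not (0 <= v <= 1):
                raise ValidationError(f"similarity {k}={v!r} outside [0, 1]")


def summarize(
    metrics: EvaluationReport | list[SampleMetrics],
    tool: str,
    scenario: str = "",
    space: str = "",
) -> ToolSummary:
    """Medians across samples of every metric; NaN excluded with counts."""
    if isinstance(metrics, EvaluationReport):
        per_sample = metrics.per_sample
    else:
        if not metrics:
            raise ValidationError("summarize: empty metric list")
        per_sample = pd.DataFrame(
            [{f: getattr(m, f) for f in ["sample_id", *_METRIC_FIELDS]} for m in metrics]
        ).set_index("sample_id")
    if per_sample.empty:
        raise ValidationError("summarize: empty metric list")
    medians, n_missing = {}, {}
    for col in per_sample.columns:
        vals = per_sample[col].to_numpy(dtype=float)
        defined = vals[~np.isnan(vals)]
        medians[col] = float(np.median(defined)) if defined.size else float("nan")
        n_missing[col] = int(np.isnan(vals).sum())
    return ToolSummary(
        tool=tool, scenario=scenario, space=space,
        medians=medians, n_missing=n_missing, n_samples=len(per_sample),
    )


def _bc_similarity(u: float, v: float) -> float:
    if u + v == 0:
        return float("nan")
    return 1.0 - abs(u - v) / (u + v)


def to_similarities(
    summary: ToolSummary, richness_truth: float, shannon_truth: float
) -> dict[str, float]:
    """[0, 1] similarity per metric (higher = better); stored on the summary.

    ``richness_truth`` / ``shannon_truth`` are the scenario's median truth
    values; the estimates are reconstructed from the median differences.
    """
    if richness_truth <= 0 or shannon_truth <= 0:
        raise ValidationError("truth richness and Shannon must be positive")
    m = summary.medians
    sims = {
        "richness": _bc_similarity(richness_truth, richness_truth + m["richness_diff"]),
        "shannon": _bc_similarity(shannon_truth, shannon_truth + m["shannon_diff"]),
        "bray_curtis": 1.0 - m["bray_curtis"],
        "unifrac": 1.0 - m["unifrac"] if not np.isnan(m["unifrac"]) else float("nan"),
        "sensitivity": m["sensitivity"],
        "precision": m["precision"],
        "tpra": 1.0 - m["fpra"],
    }
    summary.similarities = sims
    return sims


def rank_report(summaries: list[ToolSummary]) -> dict[str, list[dict]]:
    """Per-metric ranking of tools by descending similarity; ties share a rank."""
    if len(summaries) < 2:
        raise ValidationError("rank_report needs at least 2 summaries")
    for s in summaries:
        if not s.similarities:
            raise ValidationError(f"summary for {s.tool!r} has no similarities")
    report: dict[str, list[dict]] = {}
    for metric in SIMILARITY_METRICS:
        entries = [
            (s.tool, s.similarities.get(metric, float("nan"))) for s in summaries
        ]
        defined = [(t, v) for t, v in entries if not np.isnan(v)]
        defined.sort(key=lambda tv: (-tv[1], tv[0]))
        ranked, rank = [], 0
        for i, (tool, val) in enumerate(defined):
            if i == 0 or val < defined[i - 1][1]:
                rank = i + 1
            ranked.append({"tool": tool, "similarity": float(val), "rank": rank})
        report[metric] = ranked
    return report


def write_rank_report(report: dict[str, list[dict]], tsv_path=None, json_path=None) -> None:
    if json_path is not None:
        with open(json_path, "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
    if tsv_path is not None:
        rows = [
            {"metric": metric, **entry}
            for metric, entries in report.items()
            for entry in entries
        ]
        pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)
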