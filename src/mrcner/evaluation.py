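"""Entity-level exact-match scoring and run aggregation.

A prediction counts only when sentence, boundaries and label all coincide
with a gold span (no partial credit).  Overall figures are micro-averaged;
per-label breakdowns are reported alongside.  Run aggregates report mean,
sample (n-1) standard deviation and max, matching "Mean +/- std" / "Max"
table columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .corpus_io import EntitySpan


@dataclass(frozen=True)
class MatchCounts:
    TP: int = 0
    FP: int = 0
    FN: int = 0

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN) < 0:
            raise ValueError("counts must be non-negative")

    def __add__(self, other: "MatchCounts") -> "MatchCounts":
        return MatchCounts(self.TP + other.TP, self.FP + other.FP, self.FN + other.FN)


@dataclass(frozen=True)
class EvalReport:
    precision: float
    recall: float
    f1: float
    counts: MatchCounts
    degenerate: bool = False  # all-zero counts: P/R/F1 defined as 0
    per_label: dict = field(default_factory=dict)


def count_matches(
    pred: Sequence[Iterable[EntitySpan]], gold: Sequence[Iterable[EntitySpan]]
) -> MatchCounts:
    """One-to-one exact matching of aligned per-sentence span sets."""
    if len(pred) != len(gold):
        raise ValueError(f"pred has {len(pred)} sentences, gold {len(gold)}")
    tp = fp = fn = 0
    for p, g in zip(pred, gold):
        p, g = set(p), set(g)
        inter = len(p & g)
        tp += inter
        fp += len(p) - inter
        fn += len(g) - inter
    return MatchCounts(tp, fp, fn)


def score(counts: MatchCounts) -> EvalReport:
    """P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R); zero denominators
    yield 0 with the degenerate flag set."""
    degenerate = counts.TP + counts.FP + counts.FN == 0
    p = counts.TP / (counts.TP + counts.FP) if counts.TP + counts.FP else 0.0
    r = counts.TP / (counts.TP + counts.FN) if counts.TP + counts.FN else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return EvalReport(p, r, f1, counts, degenerate=degenerate)


def evaluate(
    pred: Sequence[Iterable[EntitySpan]],
    gold: Sequence[Iterable[EntitySpan]],
    labels: Iterable[str] | None = None,
) -> EvalReport:
    """Micro-averaged report with a per-label breakdown."""
    micro = count_matches(pred, gold)
    if labels is None:
        labels = sorted(
            {s.label for spans in pred for s in spans}
            | {s.label for spans in gold for s in spans}
        )
    per_label = {}
    for lab in labels:
        sub = count_matches(
            [{s for s in spans if s.label == lab} for spans in pred],
            [{s for s in spans if s.label == lab} for spans in gold],
        )
        per_label[lab] = score(sub)
    overall = score(micro)
    return EvalReport(
        overall.precision, overall.recall, overall.f1, micro,
        degenerate=overall.degenerate, per_label=per_label,
    )


@dataclass(frozen=True)
class RunAggregate:
    mean: float
    std: float
    max: float
    n_runs: int

    def __str__(self) -> str:  # table style: "88.20 +/- 0.20"
        return f"{self.mean:.2f} ± {self.std:.2f} (max {self.max:.2f}, n={self.n_runs})"


def aggregate_runs(f1s: Sequence[float]) -> RunAggregate:
    """Mean, sample (n-1) std and max over per-run F1 values."""
    if len(f1s) == 0:
        raise ValueError("aggregate_runs requires at least one run")
    arr = np.asarray(f1s, dtype=float)
    std = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return RunAggregate(float(arr.mean()), std, float(arr.max()), len(arr))


def format_report(report: EvalReport, percent: bool = True) -> str:
    """Tab-separated P/R/F1 table, micro totals plus per-label rows,
    formatted to two decimals."""
    k = 100.0 if percent else 1.0
    lines = ["label\tprecision\trecall\tf1\tTP\tFP\tFN"]

    def row(name: str, r: EvalReport) -> str:
        c = r.counts
        return (
            f"{name}\t{r.precision * k:.2f}\t{r.recall * k:.2f}\t{r.f1 * k:.2f}"
            f"\t{c.TP}\t{c.FP}\t{c.FN}"
        )

    lines.append(row("micro", report))
    for lab, sub in report.per_label.items():
        lines.append(row(lab, sub))
    return "\n".join(lines)


def report_to_dict(report: EvalReport) -> dict:
    return {
        "precision": report.precision,
        "recall": report.recall,
        "f1": report.f1,
        "TP": report.counts.TP,
        "FP": report.counts.FP,
        "FN": report.counts.FN,
        "degenerate": report.degenerate,
        "per_label": {
            lab: {
                "precision": r.precision,
                "recall": r.recall,
                "f1": r.f1,
                "TP": r.counts.TP,
                "FP": r.counts.FP,
                "FN": r.counts.FN,
            }
            for lab, r in report.per_label.items()
        },
    }
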