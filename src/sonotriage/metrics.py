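"""Pixel-wise segmentation performance metrics.

Every pixel of a prediction mask is compared one-vs-rest against the ground
truth for each class (background included as its own class), giving TP/FP/
TN/FN tallies from which five standard metrics are computed:

    accuracy  = (TP + TN) / (TP + FN + TN + FP)
    precision = TP / (FP + TP)
    recall    = TP / (FN + TP)
    IOU       = TP / (TP + FP + FN)
    Dice      = 2 TP / (2 TP + FP + FN)

Zero-denominator cases (e.g. a class absent from both masks) produce NaN —
an explicit undefined marker that aggregation skips — never an exception or
a silent zero.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts",
    "confusion_counts",
    "compute_metrics",
    "aggregate",
    "MetricReport",
    "METRIC_NAMES",
]

METRIC_NAMES = ("accuracy", "precision", "recall", "iou", "dice")


@dataclass
class ConfusionCounts:
    """Per-class one-vs-rest pixel tallies; ``total`` is the pixel count."""

    counts: dict[str, dict[str, int]] = field(default_factory=dict)
    total: int = 0

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        merged = {}
        for name in set(self.counts) | set(other.counts):
            a = self.counts.get(name, dict.fromkeys("tp fp tn fn".split(), 0))
            b = other.counts.get(name, dict.fromkeys("tp fp tn fn".split(), 0))
            merged[name] = {k: a[k] + b[k] for k in ("tp", "fp", "tn", "fn")}
        return ConfusionCounts(merged, self.total + other.total)


def confusion_counts(
    pred: np.ndarray, truth: np.ndarray, class_table: dict[str, int]
) -> ConfusionCounts:
    """Tally TP/FP/TN/FN per class by comparing every pixel one-vs-rest."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"mask shape mismatch: {pred.shape} vs {truth.shape}")
    valid = set(class_table.values())
    present = set(np.unique(pred)) | set(np.unique(truth))
    if not present <= valid:
        raise ValueError(f"labels {sorted(present - valid)} not in class table")
    total = pred.size
    out: dict[str, dict[str, int]] = {}
    for name, label in class_table.items():
        p = pred == label
        t = truth == label
        tp = int(np.count_nonzero(p & t))
        fp = int(np.count_nonzero(p & ~t))
        fn = int(np.count_nonzero(~p & t))
        out[name] = {"tp": tp, "fp": fp, "tn": total - tp - fp - fn, "fn": fn}
    return ConfusionCounts(out, total)


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


@dataclass
class MetricReport:
    """Per-class metric rows plus summary rows, with NaN as undefined."""

    per_class: dict[str, dict[str, float]]

    def to_frame(self, include_summaries: bool = True) -> pd.DataFrame:
        rows = dict(self.per_class)
        if include_summaries:
            feats = aggregate(self, include_background=False)
            alls = aggregate(self, include_background=True)
            rows["feature_average"] = {m: feats[m] for m in METRIC_NAMES}
            rows["all_class_average"] = {m: alls[m] for m in METRIC_NAMES}
        return pd.DataFrame.from_dict(rows, orient="index")[list(METRIC_NAMES)]


def compute_metrics(counts: ConfusionCounts) -> MetricReport:
    """Apply the five metric formulas to each class's tallies."""
    per_class = {}
    for name, c in counts.counts.items():
        tp, fp, tn, fn = c["tp"], c["fp"], c["tn"], c["fn"]
        per_class[name] = {
            "accuracy": _safe_div(tp + tn, tp + fn + tn + fp),
            "precision": _safe_div(tp, fp + tp),
            "recall": _safe_div(tp, fn + tp),
            "iou": _safe_div(tp, tp + fp + fn),
            "dice": _safe_div(2 * tp, 2 * tp + fp + fn),
        }
    return MetricReport(per_class)


def aggregate(report: MetricReport, include_background: bool) -> dict[str, float]:
    """Macro (unweighted) mean over classes, skipping undefined entries.

    Returns the five means plus ``n_classes`` and per-metric ``n_skipped``
    bookkeeping.  Background is included or excluded by flag; per-class rows
    are never mutated.
    """
    names = [
        n for n in report.per_class if include_background or n != "background"
    ]
    if not names:
        raise ValueError("no classes to aggregate")
    out: dict[str, float] = {"n_classes": len(names)}
    for metric in METRIC_NAMES:
        vals = np.array([report.per_class[n][metric] for n in names], dtype=float)
        defined = vals[~np.isnan(vals)]
        out[metric] = float(defined.mean()) if defined.size else float("nan")
        out[f"{metric}_n_skipped"] = int(np.isnan(vals).sum())
    return out
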