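"""Segmentation metrics from pixel confusion counts.

All statistics derive from the per-image tallies of true/false
positives/negatives between a predicted and a reference binary mask:

* Dice  = 2TP / (FP + 2TP + FN)
* IoU_i = TP_i / (FP_i + TP_i + FN_i), mIoU = mean over classes
  (binary task: background and nodule)
* Precision = TP / (TP + FP), Recall = TP / (TP + FN)
* F1 = 2 * Precision * Recall / (Precision + Recall)

For a single binary pair Dice and F1 are algebraically identical; both
are reported because aggregation over a set can differ in general.
Zero-denominator convention: a metric comparing two empty masks is 1.0
(perfect agreement), otherwise 0.0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

METRIC_NAMES = ("dice", "miou", "precision", "recall", "f1")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _validate_binary(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    bad = ~np.isin(arr, (0, 1))
    if bad.any():
        raise ValueError(f"{name} must contain only 0/1 values")
    return arr.astype(bool)


def confusion_counts(pred_mask: np.ndarray, gt_mask: np.ndarray) -> ConfusionCounts:
    """Exact pixel tallies of TP/FP/FN/TN between two binary masks."""
    pred = _validate_binary(pred_mask, "pred_mask")
    gt = _validate_binary(gt_mask, "gt_mask")
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
    tp = int(np.count_nonzero(pred & gt))
    fp = int(np.count_nonzero(pred & ~gt))
    fn = int(np.count_nonzero(~pred & gt))
    tn = int(np.count_nonzero(~pred & ~gt))
    return ConfusionCounts(tp, fp, fn, tn)


def _ratio(num: float, den: float, both_empty: bool) -> float:
    if den == 0:
        return 1.0 if both_empty else 0.0
    return num / den


def dice(c: ConfusionCounts) -> float:
    return _ratio(2 * c.tp, c.fp + 2 * c.tp + c.fn, c.tp + c.fp + c.fn == 0)


def precision(c: ConfusionCounts) -> float:
    return _ratio(c.tp, c.tp + c.fp, c.tp + c.fp + c.fn == 0)


def recall(c: ConfusionCounts) -> float:
    return _ratio(c.tp, c.tp + c.fn, c.tp + c.fp + c.fn == 0)


def f1(c: ConfusionCounts) -> float:
    p, r = precision(c), recall(c)
    if p + r == 0:
        return 1.0 if c.tp + c.fp + c.fn == 0 else 0.0
    return 2 * p * r / (p + r)


def iou(c: ConfusionCounts) -> float:
    return _ratio(c.tp, c.fp + c.tp + c.fn, c.tp + c.fp + c.fn == 0)


def miou(per_class_counts: list[ConfusionCounts]) -> float:
    """Mean IoU over classes, one ConfusionCounts per class with that
    class treated as positive."""
    if not per_class_counts:
        raise ValueError("need at least one class")
    return float(np.mean([iou(c) for c in per_class_counts]))


def binary_miou(pred_mask: np.ndarray, gt_mask: np.ndarray) -> float:
    """mIoU over {background, nodule} for one binary mask pair."""
    fg = confusion_counts(pred_mask, gt_mask)
    bg = confusion_counts(1 - np.asarray(pred_mask), 1 - np.asarray(gt_mask))
    return miou([bg, fg])


def image_metrics(pred_mask: np.ndarray, gt_mask: np.ndarray) -> dict[str, float]:
    """All five metrics for one predicted/reference mask pair."""
    c = confusion_counts(pred_mask, gt_mask)
    return {
        "dice": dice(c),
        "miou": binary_miou(pred_mask, gt_mask),
        "precision": precision(c),
        "recall": recall(c),
        "f1": f1(c),
    }


@dataclass
class MetricReport:
    """Per-image metric table plus mean and SD per metric."""

    per_image: pd.DataFrame  # columns: image id + METRIC_NAMES (+ optional fold)

    def __post_init__(self):
        missing = set(METRIC_NAMES) - set(self.per_image.columns)
        if missing:
            raise ValueError(f"per-image table missing columns {sorted(missing)}")

    @property
    def n(self) -> int:
        return len(self.per_image)

    def mean(self) -> dict[str, float]:
        return {m: float(self.per_image[m].mean()) for m in METRIC_NAMES}

    def sd(self) -> dict[str, float]:
        return {m: float(self.per_image[m].std(ddof=1)) if self.n > 1 else 0.0
                for m in METRIC_NAMES}

    def summary(self) -> dict:
        return {"n": self.n, "mean": self.mean() if self.n else {},
                "sd": self.sd() if self.n else {}}


def report_from_masks(pred_masks, gt_masks, ids=None, fold=None) -> MetricReport:
    """Build a MetricReport from aligned sequences of binary masks."""
    preds, gts = list(pred_masks), list(gt_masks)
    if len(preds) != len(gts):
        raise ValueError("pred/gt sequences differ in length")
    rows = []
    for i, (p, g) in enumerate(zip(preds, gts)):
        row = {"image": ids[i] if ids is not None else i}
        if fold is not None:
            row["fold"] = fold
        row.update(image_metrics(p, g))
        rows.append(row)
    cols = ["image"] + (["fold"] if fold is not None else []) + list(METRIC_NAMES)
    df = pd.DataFrame(rows, columns=cols)
    return MetricReport(df)


def pr_curve(prob_maps, gt_masks, thresholds=None) -> list[tuple[float, float]]:
    """Precision-recall points, pooled over the whole set per threshold.

    Predictions are binarised at each threshold (``p >= t`` positive) and
    counts are pooled over all images before computing one
    (recall, precision) point, returned in threshold order.  With zero
    predicted positives precision is reported as 1.0.
    """
    probs, gts = list(prob_maps), list(gt_masks)
    if len(probs) != len(gts):
        raise ValueError("prob/gt sequences differ in length")
    if thresholds is None:
        thresholds = np.linspace(0.0, 1.0, 101)
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size and (thresholds.min() < 0 or thresholds.max() > 1 + 1e-6):
        raise ValueError("thresholds must lie in [0, 1]")
    points = []
    for t in thresholds:
        tp = fp = fn = 0
        for p, g in zip(probs, gts):
            p = np.asarray(p)
            g = _validate_binary(g, "gt_mask")
            if p.shape != g.shape:
                raise ValueError("probability map and mask shapes differ")
            pred = p >= t
            tp += int(np.count_nonzero(pred & g))
            fp += int(np.count_nonzero(pred & ~g))
            fn += int(np.count_nonzero(~pred & g))
        rec = tp / (tp + fn) if tp + fn else 1.0
        prec = tp / (tp + fp) if tp + fp else 1.0
        points.append((rec, prec))
    return points


def write_report(report: MetricReport, path) -> tuple[Path, Path]:
    """Write per-image rows as CSV and the summary as JSON next to it.

    ``path`` is the CSV destination; the JSON summary gets the same stem
    with a ``.json`` suffix.  Returns both paths.
    """
    csv_path = Path(path)
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    report.per_image.to_csv(csv_path, index=False)
    json_path = csv_path.with_suffix(".json")
    with open(json_path, "w") as fh:
        json.dump(report.summary(), fh, indent=2)
    return csv_path, json_path


def read_report(csv_path) -> MetricReport:
    return MetricReport(pd.read_csv(csv_path))
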