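"""Pixel-overlap segmentation metrics: Dice, Jaccard, PPV, sensitivity, F1.

All five measures derive from the per-image confusion counts between a
predicted binary mask and its ground truth. When both masks are empty
(tp + fp + fn == 0) every metric is 1 by convention: the two raters agree
that there is no lesion.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

METRIC_NAMES = ("dsc", "jsc", "ppv", "sen", "f1")


@dataclass(frozen=True)
class ConfusionCounts:
    """Joint pixel counts between predicted and true binary masks."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricReport:
    """Per-image metric tuples plus their arithmetic means."""

    per_image: List[Tuple[float, float, float, float, float]]
    mean_of_each: Tuple[float, float, float, float, float]
    n_images: int


def _validate_binary(arr: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(arr)
    uniq = np.unique(a)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValueError(f"{name} must contain only values in {{0, 1}}; got {uniq[:10]}")
    return a.astype(bool)


def confusion_counts(pred: np.ndarray, gt: np.ndarray) -> ConfusionCounts:
    """Count TP/FP/FN/TN pixels between two equally sized binary masks."""
    p = np.asarray(pred)
    g = np.asarray(gt)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs gt {g.shape}")
    pb = _validate_binary(p, "pred")
    gb = _validate_binary(g, "gt")
    tp = int(np.count_nonzero(pb & gb))
    fp = int(np.count_nonzero(pb & ~gb))
    fn = int(np.count_nonzero(~pb & gb))
    tn = int(np.count_nonzero(~pb & ~gb))
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def dice(c: ConfusionCounts) -> float:
    """2*TP / (2*TP + FP + FN); 1 when both masks are empty."""
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        return 1.0
    return 2.0 * c.tp / denom


def jaccard(c: ConfusionCounts) -> float:
    """TP / (TP + FP + FN); 1 when both masks are empty."""
    denom = c.tp + c.fp + c.fn
    if denom == 0:
        return 1.0
    return c.tp / denom


def ppv(c: ConfusionCounts) -> float:
    """TP / (TP + FP). Empty-mask convention applies; 0 if no positives predicted."""
    if c.tp + c.fp + c.fn == 0:
        return 1.0
    denom = c.tp + c.fp
    if denom == 0:
        return 0.0
    return c.tp / denom


def sensitivity(c: ConfusionCounts) -> float:
    """TP / (TP + FN). Empty-mask convention applies; 0 if no true positives exist."""
    if c.tp + c.fp + c.fn == 0:
        return 1.0
    denom = c.tp + c.fn
    if denom == 0:
        return 0.0
    return c.tp / denom


def f1(c: ConfusionCounts) -> float:
    """Harmonic mean of PPV and sensitivity computed from the same counts."""
    if c.tp + c.fp + c.fn == 0:
        return 1.0
    p = ppv(c)
    s = sensitivity(c)
    if p + s == 0:
        return 0.0
    return 2.0 * p * s / (p + s)


def all_metrics(c: ConfusionCounts) -> Tuple[float, float, float, float, float]:
    return (dice(c), jaccard(c), ppv(c), sensitivity(c), f1(c))


def evaluate_pair(pred: np.ndarray, gt: np.ndarray) -> Tuple[float, float, float, float, float]:
    return all_metrics(confusion_counts(pred, gt))


def evaluate_dataset(pairs: Sequence[Tuple[np.ndarray, np.ndarray]]) -> MetricReport:
    """Per-image metrics plus their arithmetic means over a (pred, gt) list."""
    if len(pairs) == 0:
        raise ValueError("evaluate_dataset requires at least one (pred, gt) pair")
    per_image = [evaluate_pair(p, g) for p, g in pairs]
    arr = np.asarray(per_image, dtype=float)
    means = tuple(float(v) for v in arr.mean(axis=0))
    return MetricReport(per_image=per_image, mean_of_each=means, n_images=len(pairs))


def write_report_csv(report: MetricReport, ids: Sequence[str], path) -> None:
    """CSV with one row per image and a final row of means."""
    if len(ids) != report.n_images:
        raise ValueError("ids and report lengths differ")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image_id", *METRIC_NAMES])
        for image_id, row in zip(ids, report.per_image):
            writer.writerow([image_id, *[f"{v:.6f}" for v in row]])
        writer.writerow(["mean", *[f"{v:.6f}" for v in report.mean_of_each]])
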