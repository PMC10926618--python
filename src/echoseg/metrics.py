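"""Confusion-matrix based evaluation indices for multi-class segmentation.

All scores derive from a single C×C pixel-count confusion matrix whose entry
``(t, p)`` counts pixels of true class ``t`` predicted as class ``p``; the
one-vs-rest marginals give per-class TP/FP/FN/TN.  Degenerate 0/0 ratios
(class absent from both maps) score 1, keeping absent-class entries
well-defined; means may optionally exclude such classes.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "confusion_matrix",
    "dice",
    "iou",
    "miou",
    "pixel_accuracy",
    "cpa",
    "MetricsReport",
    "compute_report",
]


@dataclass
class ConfusionMatrix:
    counts: np.ndarray
    num_classes: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (self.num_classes, self.num_classes):
            raise ValueError("counts must be C×C")
        if (self.counts < 0).any():
            raise ValueError("confusion-matrix entries must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def marginals(self, c: int) -> tuple[int, int, int, int]:
        """One-vs-rest (TP, FP, FN, TN) of class ``c``."""
        if not 0 <= c < self.num_classes:
            raise IndexError(f"class {c} out of range for C={self.num_classes}")
        tp = int(self.counts[c, c])
        fp = int(self.counts[:, c].sum()) - tp
        fn = int(self.counts[c, :].sum()) - tp
        tn = self.total - tp - fp - fn
        return tp, fp, fn, tn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if other.num_classes != self.num_classes:
            raise ValueError("class-count mismatch")
        return ConfusionMatrix(self.counts + other.counts, self.num_classes)


def confusion_matrix(pred: np.ndarray, truth: np.ndarray, num_classes: int) -> ConfusionMatrix:
    """Pixel-count confusion matrix; entry ``(t, p)`` = |{truth=t ∧ pred=p}|."""
    pred = np.asarray(pred).ravel()
    truth = np.asarray(truth).ravel()
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    for name, a in (("pred", pred), ("truth", truth)):
        if a.size and (a.min() < 0 or a.max() >= num_classes):
            raise ValueError(f"{name} contains labels outside [0, {num_classes})")
    counts = np.bincount(
        truth.astype(np.int64) * num_classes + pred.astype(np.int64),
        minlength=num_classes * num_classes,
    ).reshape(num_classes, num_classes)
    return ConfusionMatrix(counts, num_classes)


def _safe_ratio(num: float, den: float) -> float:
    return 1.0 if den == 0 else num / den


def dice(cm: ConfusionMatrix, c: int) -> float:
    """Dice coefficient 2TP/(2TP+FP+FN) of class ``c``; 0/0 = 1."""
    tp, fp, fn, _ = cm.marginals(c)
    return _safe_ratio(2 * tp, 2 * tp + fp + fn)


def iou(cm: ConfusionMatrix, c: int) -> float:
    """Intersection over union TP/(TP+FP+FN) of class ``c``; 0/0 = 1."""
    tp, fp, fn, _ = cm.marginals(c)
    return _safe_ratio(tp, tp + fp + fn)


def cpa(cm: ConfusionMatrix, c: int) -> float:
    """Category pixel accuracy (precision) TP/(TP+FP) of class ``c``; 0/0 = 1."""
    tp, fp, _, _ = cm.marginals(c)
    return _safe_ratio(tp, tp + fp)


def _mean(values: list[float], present: list[bool], include_absent: bool) -> float:
    if include_absent:
        return float(np.mean(values))
    kept = [v for v, p in zip(values, present) if p]
    return float(np.mean(kept)) if kept else 1.0


def _present_mask(cm: ConfusionMatrix) -> list[bool]:
    return [
        (cm.counts[c, :].sum() + cm.counts[:, c].sum()) > 0 for c in range(cm.num_classes)
    ]


def miou(cm: ConfusionMatrix, include_absent: bool = True) -> float:
    """Unweighted mean IOU over all classes (background included).

    ``include_absent=False`` drops classes absent from both maps from
    the mean instead of scoring them 1.
    """
    vals = [iou(cm, c) for c in range(cm.num_classes)]
    return _mean(vals, _present_mask(cm), include_absent)


def mean_dice(cm: ConfusionMatrix, include_absent: bool = True) -> float:
    """Unweighted mean Dice over all classes."""
    vals = [dice(cm, c) for c in range(cm.num_classes)]
    return _mean(vals, _present_mask(cm), include_absent)


def pixel_accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of correctly predicted pixels, trace/total."""
    if cm.total == 0:
        raise ValueError("pixel accuracy undefined on an empty confusion matrix")
    return float(np.trace(cm.counts)) / cm.total


@dataclass
class MetricsReport:
    """Per-class and aggregate segmentation scores plus the source matrix."""

    class_names: list[str]
    per_class: dict[str, list[float]]  # keys: dice, iou, cpa
    aggregates: dict[str, float]  # keys: mean_dice, miou, pixel_accuracy
    cm: ConfusionMatrix = field(repr=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "class_names": self.class_names,
            "per_class": self.per_class,
            "aggregates": self.aggregates,
            "confusion_matrix": self.cm.counts.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["class", "dice", "iou", "cpa"])
            for i, name in enumerate(self.class_names):
                w.writerow(
                    [
                        name,
                        f"{self.per_class['dice'][i]:.6f}",
                        f"{self.per_class['iou'][i]:.6f}",
                        f"{self.per_class['cpa'][i]:.6f}",
                    ]
                )
            for key in sorted(self.aggregates):
                w.writerow([key, f"{self.aggregates[key]:.6f}", "", ""])


def compute_report(
    cm: ConfusionMatrix,
    class_names: list[str] | None = None,
    include_absent: bool = True,
) -> MetricsReport:
    C = cm.num_classes
    names = class_names if class_names is not None else [f"class{c}" for c in range(C)]
    if len(names) != C:
        raise ValueError("class_names length must equal num_classes")
    per_class = {
        "dice": [dice(cm, c) for c in range(C)],
        "iou": [iou(cm, c) for c in range(C)],
        "cpa": [cpa(cm, c) for c in range(C)],
    }
    aggregates = {
        "mean_dice": mean_dice(cm, include_absent),
        "miou": miou(cm, include_absent),
        "pixel_accuracy": pixel_accuracy(cm),
    }
    return MetricsReport(names, per_class, aggregates, cm)
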