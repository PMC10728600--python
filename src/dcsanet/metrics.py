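"""Segmentation metrics: per-class confusion counts, IoU/MIoU, and the
analytic cross-entropy used to monitor training.

MIoU is the unweighted mean of per-class TP / (TP + FN + FP) over all
classes, background included.  A class absent from both the prediction and
the truth has TP = FP = FN = 0; its ratio is undefined (0/0) and the class
is excluded from the mean rather than scored 0 or 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "LossInputs",
    "cross_entropy_loss",
    "confusion_from_masks",
    "miou",
]


@dataclass
class ConfusionCounts:
    """Per-class one-vs-rest pixel counts; arrays indexed by class."""

    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray

    @property
    def num_classes(self):
        return len(self.tp)

    @property
    def total_pixels(self):
        return int(self.tp[0] + self.fp[0] + self.fn[0] + self.tn[0])

    def __add__(self, other):
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn, self.tn + other.tn
        )

    @classmethod
    def zeros(cls, num_classes):
        z = lambda: np.zeros(num_classes, dtype=np.int64)
        return cls(z(), z(), z(), z())


@dataclass
class MetricsReport:
    per_class_iou: list
    miou: float
    confusion: ConfusionCounts


@dataclass(frozen=True)
class LossInputs:
    """Predicted per-pixel class probabilities and one-hot targets.

    ``probs`` and ``onehot`` both have shape (..., M) with the class axis
    last; probabilities sum to 1 over the class axis, the targets carry a
    single 1 per pixel.
    """

    probs: np.ndarray
    onehot: np.ndarray

    def __post_init__(self):
        if self.probs.shape != self.onehot.shape:
            raise ValueError(
                f"probability shape {self.probs.shape} does not match targets {self.onehot.shape}"
            )


def cross_entropy_loss(inputs: LossInputs) -> float:
    """-(1/N) sum_i sum_c y_ic log p_ic with N the number of pixels."""
    p = np.clip(inputs.probs, np.finfo(float).eps, None)
    n_pixels = int(np.prod(inputs.probs.shape[:-1]))
    return float(-(inputs.onehot * np.log(p)).sum() / n_pixels)


def confusion_from_masks(pred: np.ndarray, true: np.ndarray, num_classes: int) -> ConfusionCounts:
    """Accumulate per-class TP/FP/FN/TN between two integer label masks."""
    pred = np.asarray(pred)
    true = np.asarray(true)
    if pred.shape != true.shape:
        raise ValueError(f"mask shapes differ: {pred.shape} vs {true.shape}")
    if pred.size == 0:
        raise ValueError("empty masks")
    for name, m in (("pred", pred), ("true", true)):
        if m.min() < 0 or m.max() >= num_classes:
            raise ValueError(f"{name} mask contains labels outside [0, {num_classes})")
    joint = np.bincount(
        (true.ravel().astype(np.int64) * num_classes + pred.ravel()), minlength=num_classes**2
    ).reshape(num_classes, num_classes)  # joint[t, p]
    tp = np.diag(joint).astype(np.int64)
    fp = joint.sum(axis=0) - tp
    fn = joint.sum(axis=1) - tp
    tn = joint.sum() - tp - fp - fn
    return ConfusionCounts(tp, fp, fn, tn)


def miou(confusion: ConfusionCounts) -> MetricsReport:
    """Mean IoU over all classes; 0/0 classes (absent everywhere) excluded."""
    denom = confusion.tp + confusion.fp + confusion.fn
    present = denom > 0
    iou = np.full(confusion.num_classes, np.nan)
    iou[present] = confusion.tp[present] / denom[present]
    mean = float(iou[present].mean()) if present.any() else float("nan")
    return MetricsReport(per_class_iou=iou.tolist(), miou=mean, confusion=confusion)
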