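"""Segmentation evaluation metrics from pixel confusion counts.

For binary lesion masks (foreground = lesion = positive class) the package
reports three standard quantities:

* mean pixel accuracy, ``mPA = (1/k) * sum_j n_jj / t_j`` — the mean over
  classes of per-class recall, where ``n_jj`` is the number of pixels
  correctly classified as class ``j`` and ``t_j`` the number of
  ground-truth pixels of class ``j``; classes absent from the ground truth
  are excluded from the mean;
* intersection over union, ``IoU = |X ∩ Y| / |X ∪ Y| = TP / (TP+FP+FN)``,
  reported per class and as the two-class mean (mIoU);
* Dice similarity, ``Dice = 2·TP / (2·TP+FP+FN)``, a monotone transform of
  the foreground IoU (``Dice = 2·IoU / (1+IoU)``).

When both masks are empty the union is empty and the metric is defined as
1.0 (a correct empty prediction is a perfect prediction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

from .core import SegmentationMask, check_aligned

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "confusion_counts",
    "pixel_accuracy_per_class",
    "mean_pixel_accuracy",
    "iou_score",
    "dice_score",
    "evaluate_pair",
    "evaluate_dataset",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel tallies with lesion foreground as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            tp=self.tp + other.tp,
            fp=self.fp + other.fp,
            fn=self.fn + other.fn,
            tn=self.tn + other.tn,
        )


def confusion_counts(pred: SegmentationMask, truth: SegmentationMask) -> ConfusionCounts:
    """Exhaustive pixel-by-pixel confusion tally of a prediction vs truth."""
    check_aligned(pred, truth, "prediction and truth masks")
    p = pred.pixels.astype(bool)
    t = truth.pixels.astype(bool)
    return ConfusionCounts(
        tp=int(np.count_nonzero(p & t)),
        fp=int(np.count_nonzero(p & ~t)),
        fn=int(np.count_nonzero(~p & t)),
        tn=int(np.count_nonzero(~p & ~t)),
    )


def pixel_accuracy_per_class(
    correct: Sequence[int], truth_totals: Sequence[int]
) -> tuple[float, list[Optional[float]]]:
    """Mean of per-class pixel recall, skipping classes absent from the truth.

    ``correct[j]`` is the count of pixels correctly classified as class
    ``j`` and ``truth_totals[j]`` the ground-truth pixel count of class
    ``j``. Returns ``(mPA, per_class)`` where an absent class contributes
    ``None`` to ``per_class`` and is excluded from the mean.
    """
    if len(correct) != len(truth_totals) or len(correct) == 0:
        raise ValueError("need equal-length, non-empty per-class counts")
    per_class: list[Optional[float]] = []
    present: list[float] = []
    for n_jj, t_j in zip(correct, truth_totals):
        if t_j == 0:
            per_class.append(None)
        else:
            acc = n_jj / t_j
            per_class.append(acc)
            present.append(acc)
    if not present:
        raise ValueError("no class has ground-truth pixels")
    return float(np.mean(present)), per_class


def mean_pixel_accuracy(counts: ConfusionCounts) -> float:
    """Two-class mPA (mean of foreground and background recall)."""
    mpa, _ = pixel_accuracy_per_class(
        correct=[counts.tn, counts.tp],
        truth_totals=[counts.tn + counts.fp, counts.tp + counts.fn],
    )
    return mpa


def iou_score(counts: ConfusionCounts) -> float:
    """Foreground IoU, TP/(TP+FP+FN); 1.0 when the union is empty."""
    union = counts.tp + counts.fp + counts.fn
    return 1.0 if union == 0 else counts.tp / union


def dice_score(counts: ConfusionCounts) -> float:
    """Foreground Dice, 2TP/(2TP+FP+FN); 1.0 when both masks are empty."""
    denom = 2 * counts.tp + counts.fp + counts.fn
    return 1.0 if denom == 0 else 2 * counts.tp / denom


def _background(counts: ConfusionCounts) -> ConfusionCounts:
    """Confusion counts with the class roles swapped."""
    return ConfusionCounts(tp=counts.tn, fp=counts.fn, fn=counts.fp, tn=counts.tp)


def _summary(counts: ConfusionCounts) -> dict[str, float]:
    fg_iou = iou_score(counts)
    bg_iou = iou_score(_background(counts))
    return {
        "mpa": mean_pixel_accuracy(counts),
        "pixel_accuracy": (counts.tp + counts.tn) / counts.total,
        "fg_iou": fg_iou,
        "bg_iou": bg_iou,
        "miou": (fg_iou + bg_iou) / 2.0,
        "dice": dice_score(counts),
    }


@dataclass(eq=False)
class MetricReport:
    """Dataset-level metric summary plus the per-image table behind it."""

    mpa: float
    miou: float
    fg_iou: float
    dice: float
    pixel_accuracy: float
    mode: Literal["micro", "per_image"]
    per_image: dict[str, dict[str, float]] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "mode": self.mode,
            "mpa": self.mpa,
            "miou": self.miou,
            "fg_iou": self.fg_iou,
            "dice": self.dice,
            "pixel_accuracy": self.pixel_accuracy,
            "per_image": self.per_image,
        }


def evaluate_pair(pred: SegmentationMask, truth: SegmentationMask) -> dict[str, float]:
    """All metrics for one prediction/truth pair."""
    return _summary(confusion_counts(pred, truth))


def evaluate_dataset(
    preds: Sequence[SegmentationMask],
    truths: Sequence[SegmentationMask],
    mode: Literal["micro", "per_image"] = "micro",
    ids: Optional[Sequence[str]] = None,
) -> MetricReport:
    """Aggregate metrics over a dataset.

    ``micro`` pools confusion counts over all pixels of all images before
    applying the metric formulas; ``per_image`` computes metrics per image
    and averages the values. For a single image the two agree exactly.
    """
    if len(preds) != len(truths):
        raise ValueError("preds and truths must have equal length")
    if len(preds) == 0:
        raise ValueError("cannot evaluate an empty dataset")
    if mode not in ("micro", "per_image"):
        raise ValueError(f"unknown aggregation mode {mode!r}")
    if ids is None:
        ids = [f"image-{i:04d}" for i in range(len(preds))]

    per_image: dict[str, dict[str, float]] = {}
    pooled = ConfusionCounts(0, 0, 0, 0)
    for img_id, pred, truth in zip(ids, preds, truths):
        counts = confusion_counts(pred, truth)
        per_image[str(img_id)] = _summary(counts)
        pooled = pooled + counts

    if mode == "micro":
        agg = _summary(pooled)
    else:
        keys = ("mpa", "pixel_accuracy", "fg_iou", "bg_iou", "miou", "dice")
        agg = {k: float(np.mean([row[k] for row in per_image.values()])) for k in keys}
    return MetricReport(
        mpa=agg["mpa"],
        miou=agg["miou"],
        fg_iou=agg["fg_iou"],
        dice=agg["dice"],
        pixel_accuracy=agg["pixel_accuracy"],
        mode=mode,
        per_image=per_image,
    )
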