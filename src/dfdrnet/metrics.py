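"""Segmentation evaluation: per-image Dice, IoU, sensitivity, specificity.

Counts treat foreground (mask value 1) as the positive class.  Dataset
scores are arithmetic means of per-image metrics — the dominant
convention for the polyp benchmarks — not pooled-pixel ratios.

Degenerate images are handled by the empty-reference rule: a metric
whose reference set is empty scores 1 when the prediction agrees (e.g.
sensitivity on a lesion-free image with no false positives... reference
empty and prediction empty), else 0.  This matters because synthetic
datasets may contain lesion-free images.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion_counts",
    "segmentation_metrics",
    "evaluate_dataset",
    "write_report",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricsReport:
    dice: float
    iou: float
    sensitivity: float
    specificity: float
    n_images: int = 1


def _as_binary(mask: np.ndarray, name: str) -> np.ndarray:
    mask = np.asarray(mask)
    vals = np.unique(mask)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError(f"{name} must be binary with values in {{0,1}}, found {vals[:8]}")
    return mask.astype(np.int64)


def confusion_counts(pred: np.ndarray, gt: np.ndarray) -> ConfusionCounts:
    """Pixelwise confusion counts between two binary masks of equal shape."""
    pred = _as_binary(pred, "pred")
    gt = _as_binary(gt, "gt")
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
    tp = int(np.sum((pred == 1) & (gt == 1)))
    fp = int(np.sum((pred == 1) & (gt == 0)))
    fn = int(np.sum((pred == 0) & (gt == 1)))
    tn = int(np.sum((pred == 0) & (gt == 0)))
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def segmentation_metrics(c: ConfusionCounts) -> MetricsReport:
    """Dice, IoU, sensitivity and specificity from confusion counts.

    ``dice = 2tp/(2tp+fp+fn)``, ``iou = tp/(tp+fp+fn)``,
    ``sensitivity = tp/(tp+fn)``, ``specificity = tn/(tn+fp)``.  When a
    denominator is zero the metric is 1 if the prediction agrees with
    the (empty) reference set, else 0.
    """
    if min(c.tp, c.fp, c.fn, c.tn) < 0:
        raise ValueError("confusion counts must be non-negative")
    no_fg = c.tp + c.fn == 0  # ground truth has no lesion pixels
    no_bg = c.tn + c.fp == 0
    dice = 2.0 * c.tp / (2.0 * c.tp + c.fp + c.fn) if not (no_fg and c.fp == 0) else 1.0
    iou = c.tp / (c.tp + c.fp + c.fn) if c.tp + c.fp + c.fn > 0 else 1.0
    sens = c.tp / (c.tp + c.fn) if not no_fg else (1.0 if c.fp == 0 else 0.0)
    spec = c.tn / (c.tn + c.fp) if not no_bg else (1.0 if c.fn == 0 else 0.0)
    return MetricsReport(dice=dice, iou=iou, sensitivity=sens, specificity=spec, n_images=1)


def evaluate_dataset(model, dataset, threshold: float = 0.5, batch_size: int = 8):
    """Mean per-image metrics of a model over (image, mask) samples.

    Predictions are binarized by argmax over the two class posteriors,
    which for binary output equals thresholding the foreground
    probability at 0.5.  Returns ``(MetricsReport, per_image_reports)``.
    """
    samples = list(dataset)
    if not samples:
        raise ValueError("dataset is empty")
    per_image: list[MetricsReport] = []
    for i in range(0, len(samples), batch_size):
        chunk = samples[i : i + batch_size]
        imgs = np.stack([s.image for s in chunk])
        out = model.predict(imgs)
        if threshold == 0.5:
            preds = out.predicted_mask
        else:
            preds = (out.foreground_probability >= threshold).astype(np.uint8)
        for pred, s in zip(preds, chunk):
            per_image.append(segmentation_metrics(confusion_counts(pred, s.mask)))
    mean = MetricsReport(
        dice=float(np.mean([r.dice for r in per_image])),
        iou=float(np.mean([r.iou for r in per_image])),
        sensitivity=float(np.mean([r.sensitivity for r in per_image])),
        specificity=float(np.mean([r.specificity for r in per_image])),
        n_images=len(per_image),
    )
    return mean, per_image


def write_report(path_json, path_csv, mean: MetricsReport, per_image, ids=None):
    """Write the evaluation as JSON and as CSV (one row per image + summary)."""
    with open(path_json, "w") as fh:
        json.dump({"summary": asdict(mean), "per_image": [asdict(r) for r in per_image]}, fh, indent=2)
    with open(path_csv, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "dice", "iou", "sensitivity", "specificity"])
        for i, r in enumerate(per_image):
            name = ids[i] if ids else str(i)
            w.writerow([name, f"{r.dice:.6f}", f"{r.iou:.6f}", f"{r.sensitivity:.6f}", f"{r.specificity:.6f}"])
        w.writerow(["mean", f"{mean.dice:.6f}", f"{mean.iou:.6f}", f"{mean.sensitivity:.6f}", f"{mean.specificity:.6f}"])
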