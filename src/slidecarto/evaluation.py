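"""Pixelwise evaluation of class maps against ground-truth rasters.

Evaluation runs at the analysis resolution.  Only pixels carrying both a
ground-truth tissue label and a predicted tissue label enter the
confusion matrix: sentinel codes (background, rejected, unclassified) and
unannotated ground truth (code 0) are excluded from both axes.  Classwise
metrics treat each class as a one-vs-rest two-class problem.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fusion import BACKGROUND, REJECTED, UNCLASSIFIED, ClassMap

__all__ = ["ConfusionMatrix", "MetricsReport", "confusion", "metrics", "rejection_report"]

_SENTINELS = (BACKGROUND, UNCLASSIFIED, REJECTED)


@dataclass
class ConfusionMatrix:
    """K x K counts; rows = ground truth, columns = prediction."""

    counts: np.ndarray
    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.class_names)
        if self.counts.shape != (k, k):
            raise ValueError(f"confusion matrix shape {self.counts.shape} != ({k}, {k})")
        if np.any(self.counts < 0):
            raise ValueError("negative confusion counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.class_names), columns=list(self.class_names))


@dataclass
class MetricsReport:
    """Overall accuracy and one-vs-rest per-class metrics.

    Per-class entries are NaN where the denominator is zero (class absent
    from ground truth or never predicted).
    """

    accuracy: float
    recall: np.ndarray
    precision: np.ndarray
    f1: np.ndarray
    class_names: tuple[str, ...]
    evaluated_pixels: int
    rejected_fraction: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"recall": self.recall, "precision": self.precision, "f1": self.f1},
            index=list(self.class_names),
        )


def _valid_codes(raster: np.ndarray, n_classes: int) -> np.ndarray:
    return (raster >= 1) & (raster <= n_classes)


def confusion(gt: np.ndarray, pred: ClassMap | np.ndarray, class_names=None) -> ConfusionMatrix:
    """Confusion matrix over pixels that are tissue-labeled on both rasters."""
    if isinstance(pred, ClassMap):
        class_names = pred.class_names
        pred_raster = pred.raster
    else:
        if class_names is None:
            raise ValueError("class_names required when pred is a bare raster")
        pred_raster = np.asarray(pred)
    class_names = tuple(class_names)
    gt = np.asarray(gt)
    if gt.shape != pred_raster.shape:
        raise ValueError(f"ground truth {gt.shape} not aligned with prediction {pred_raster.shape}")
    k = len(class_names)
    valid = _valid_codes(gt, k) & _valid_codes(pred_raster, k)
    gi = gt[valid].astype(np.int64) - 1
    pj = pred_raster[valid].astype(np.int64) - 1
    counts = np.bincount(gi * k + pj, minlength=k * k).reshape(k, k)
    return ConfusionMatrix(counts=counts, class_names=class_names)


def metrics(cm: ConfusionMatrix, rejected_fraction: float = 0.0) -> MetricsReport:
    """Accuracy plus one-vs-rest recall/precision/F1 per class."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix: no jointly labeled pixels")
    counts = cm.counts.astype(float)
    diag = np.diag(counts)
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        recall = np.where(row > 0, diag / row, np.nan)
        precision = np.where(col > 0, diag / col, np.nan)
        denom = recall + precision
        f1 = np.where(np.nan_to_num(denom) > 0, 2 * recall * precision / denom, np.nan)
    return MetricsReport(
        accuracy=float(diag.sum() / cm.total),
        recall=recall,
        precision=precision,
        f1=f1,
        class_names=cm.class_names,
        evaluated_pixels=cm.total,
        rejected_fraction=float(rejected_fraction),
    )


def rejection_report(gt: np.ndarray, pred_before: ClassMap, pred_after: ClassMap) -> dict:
    """Quantify what rejection changed, mirroring the before/after analysis.

    ``pred_after`` must equal ``pred_before`` except at pixels that became
    REJECTED.  Reports the rejected pixel fraction (relative to previously
    evaluated pixels), the change in correct and false predicted-pixel
    counts, and accuracy before/after.
    """
    before, after = pred_before.raster, pred_after.raster
    if before.shape != after.shape:
        raise ValueError("class maps not aligned")
    changed = before != after
    if np.any(changed & (after != REJECTED)):
        raise ValueError("predictions are not nested: non-rejection changes found")
    k = len(pred_before.class_names)
    gt = np.asarray(gt)
    gt_valid = _valid_codes(gt, k)

    def _counts(raster):
        valid = gt_valid & _valid_codes(raster, k)
        correct = int(np.count_nonzero(valid & (raster == gt)))
        return int(valid.sum()), correct

    n_before, correct_before = _counts(before)
    n_after, correct_after = _counts(after)
    false_before = n_before - correct_before
    false_after = n_after - correct_after
    return {
        "rejected_fraction": (n_before - n_after) / n_before if n_before else 0.0,
        "delta_correct": correct_after - correct_before,
        "delta_false": false_after - false_before,
        "correct_before": correct_before,
        "correct_after": correct_after,
        "false_before": false_before,
        "false_after": false_after,
        "accuracy_before": correct_before / n_before if n_before else float("nan"),
        "accuracy_after": correct_after / n_after if n_after else float("nan"),
    }
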