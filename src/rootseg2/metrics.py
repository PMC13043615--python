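"""Per-class IoU and Dice with means over all classes, including background.

IoU_c = TP / (TP + FP + FN) and Dice_c = 2TP / (2TP + FP + FN) from exact
integer pixel counts.  A class with an empty union (absent from both the
prediction and the truth of an image) carries no information for that image
and is excluded from that image's mean, avoiding an arbitrary 0-or-1
convention.  Dataset-level numbers are macro averages: metrics are computed
per image and then averaged over images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ConfusionCounts", "confusion", "iou_dice", "evaluate_masks"]


@dataclass
class ConfusionCounts:
    """Per-class TP / FP / FN pixel counts for one prediction-truth pair."""

    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray

    def __post_init__(self) -> None:
        for a in (self.tp, self.fp, self.fn):
            if (np.asarray(a) < 0).any():
                raise ValueError("counts must be non-negative")

    @property
    def n_classes(self) -> int:
        return len(self.tp)


def confusion(pred: np.ndarray, truth: np.ndarray, n_classes: int) -> ConfusionCounts:
    """Exact per-class confusion counts between two label masks."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    if pred.max(initial=0) >= n_classes or truth.max(initial=0) >= n_classes:
        raise ValueError(f"mask values must be < n_classes={n_classes}")
    joint = np.bincount(
        truth.ravel().astype(np.int64) * n_classes + pred.ravel().astype(np.int64),
        minlength=n_classes * n_classes,
    ).reshape(n_classes, n_classes)
    tp = np.diag(joint).copy()
    fn = joint.sum(axis=1) - tp  # truth class c predicted as something else
    fp = joint.sum(axis=0) - tp  # predicted c where truth differs
    return ConfusionCounts(tp=tp, fp=fp, fn=fn)


def iou_dice(counts: ConfusionCounts) -> dict:
    """Per-class IoU/Dice and their means over classes with non-empty union.

    Classes whose union TP+FP+FN is zero get NaN per-class values and are
    excluded from ``miou`` and ``mean_dice``.
    """
    tp = counts.tp.astype(np.float64)
    fp = counts.fp.astype(np.float64)
    fn = counts.fn.astype(np.float64)
    union = tp + fp + fn
    valid = union > 0
    iou = np.full(counts.n_classes, np.nan)
    dice = np.full(counts.n_classes, np.nan)
    iou[valid] = tp[valid] / union[valid]
    dice[valid] = 2.0 * tp[valid] / (2.0 * tp[valid] + fp[valid] + fn[valid])
    return {
        "iou": iou,
        "dice": dice,
        "miou": float(np.nanmean(iou)) if valid.any() else float("nan"),
        "mean_dice": float(np.nanmean(dice)) if valid.any() else float("nan"),
        "valid": valid,
    }


def evaluate_masks(
    pred_masks, truth_masks, n_classes: int, sample_ids=None
) -> pd.DataFrame:
    """Per-image metric rows plus a macro-average ``__mean__`` row."""
    pred_masks = list(pred_masks)
    truth_masks = list(truth_masks)
    if len(pred_masks) != len(truth_masks):
        raise ValueError("prediction and truth lists differ in length")
    if not pred_masks:
        raise ValueError("nothing to evaluate")
    if sample_ids is None:
        sample_ids = [f"sample_{i:04d}" for i in range(len(pred_masks))]
    rows = []
    for sid, p, t in zip(sample_ids, pred_masks, truth_masks):
        m = iou_dice(confusion(p, t, n_classes))
        row = {"sample": sid, "miou": m["miou"], "mean_dice": m["mean_dice"]}
        for c in range(n_classes):
            row[f"iou_{c}"] = m["iou"][c]
            row[f"dice_{c}"] = m["dice"][c]
        rows.append(row)
    df = pd.DataFrame(rows)
    mean_row = {"sample": "__mean__"}
    for col in df.columns[1:]:
        mean_row[col] = float(np.nanmean(df[col].to_numpy(dtype=float)))
    return pd.concat([df, pd.DataFrame([mean_row])], ignore_index=True)
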