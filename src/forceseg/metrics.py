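"""Segmentation evaluation: Dice, IoU, precision/recall/F1 and the boundary F1 score.

All metrics are semantic (foreground vs. background) set-overlap measures computed
per image; ``evaluate_dataset`` additionally reports unweighted means. Boundary F1
counts a boundary pixel as correct when it lies within a Euclidean tolerance of the
other mask's boundary, which rewards tight contours rather than bulk overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .losses import extract_boundary

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "confusion",
    "region_metrics",
    "boundary_f1",
    "evaluate_pair",
    "evaluate_dataset",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel-level confusion counts between a predicted and a true binary mask."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricReport:
    """Per-image metric bundle; all values in [0, 1]."""

    dice: float
    iou: float
    precision: float
    recall: float
    f1: float
    bf: float
    bf_tolerance: float = 2.0


def _as_bool(mask: np.ndarray) -> np.ndarray:
    return np.asarray(mask) > 0


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Exact integer confusion counts; shapes must match."""
    p = _as_bool(pred)
    t = _as_bool(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(np.count_nonzero(~p & ~t))
    return ConfusionCounts(tp, fp, fn, tn)


def region_metrics(counts: ConfusionCounts) -> tuple[float, float, float, float, float]:
    """(dice, iou, precision, recall, f1) from confusion counts.

    Conventions for degenerate masks: if both masks are empty every metric is 1
    (a perfect background-only prediction); if exactly one is empty, all are 0.
    """
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    pred_n = tp + fp
    truth_n = tp + fn
    if pred_n == 0 and truth_n == 0:
        return 1.0, 1.0, 1.0, 1.0, 1.0
    if pred_n == 0 or truth_n == 0:
        return 0.0, 0.0, 0.0, 0.0, 0.0
    dice = 2.0 * tp / (pred_n + truth_n)
    union = tp + fp + fn
    iou = tp / union
    precision = tp / pred_n
    recall = tp / truth_n
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return dice, iou, precision, recall, f1


def boundary_f1(pred: np.ndarray, truth: np.ndarray, tolerance: float = 2.0) -> float:
    """Boundary F1 score with a Euclidean matching tolerance in pixels.

    Boundary precision is the fraction of predicted boundary pixels within
    `tolerance` of any true boundary pixel; recall is the symmetric quantity;
    the score is their harmonic mean. Boundaries are 4-neighbour inner contours
    (the image border counts as background).
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    pb = extract_boundary(_as_bool(pred)).points
    tb = extract_boundary(_as_bool(truth)).points
    if not pb and not tb:
        return 1.0
    if not pb or not tb:
        return 0.0
    shape = np.asarray(pred).shape

    def _within(points: set, other: set) -> float:
        other_mask = np.zeros(shape, dtype=bool)
        rr, cc = zip(*other)
        other_mask[list(rr), list(cc)] = True
        # exact Euclidean distance to the nearest `other` boundary pixel
        dist = ndimage.distance_transform_edt(~other_mask)
        pts = np.array(sorted(points))
        return float(np.mean(dist[pts[:, 0], pts[:, 1]] <= tolerance))

    bp = _within(pb, tb)
    br = _within(tb, pb)
    if bp + br == 0:
        return 0.0
    return 2 * bp * br / (bp + br)


def evaluate_pair(
    pred: np.ndarray, truth: np.ndarray, tolerance: float = 2.0
) -> MetricReport:
    """Full metric bundle for one predicted/true mask pair (labels binarized)."""
    counts = confusion(pred, truth)
    dice, iou, precision, recall, f1 = region_metrics(counts)
    bf = boundary_f1(pred, truth, tolerance)
    return MetricReport(dice, iou, precision, recall, f1, bf, tolerance)


def evaluate_dataset(
    preds: Mapping[str, np.ndarray] | Sequence[np.ndarray],
    truths: Mapping[str, np.ndarray] | Sequence[np.ndarray],
    tolerance: float = 2.0,
) -> pd.DataFrame:
    """Per-image metrics plus a final unweighted ``mean`` row.

    `preds` and `truths` are parallel sequences or mappings keyed by image id;
    label maps are binarized to foreground/background before scoring.
    """
    if isinstance(preds, Mapping) != isinstance(truths, Mapping):
        raise ValueError("preds and truths must both be mappings or both sequences")
    if isinstance(preds, Mapping):
        if set(preds) != set(truths):
            raise ValueError("mismatched image ids between predictions and truth")
        ids = sorted(preds)
        pairs = [(i, preds[i], truths[i]) for i in ids]
    else:
        if len(preds) != len(truths):
            raise ValueError("mismatched number of predictions and truths")
        pairs = [(str(i), p, t) for i, (p, t) in enumerate(zip(preds, truths))]

    rows = []
    for image_id, p, t in pairs:
        rep = evaluate_pair(p, t, tolerance)
        row = {"image_id": image_id, **asdict(rep)}
        del row["bf_tolerance"]
        rows.append(row)
    df = pd.DataFrame(rows)
    mean_row = {"image_id": "mean", **df[["dice", "iou", "precision", "recall", "f1", "bf"]].mean().to_dict()}
    return pd.concat([df, pd.DataFrame([mean_row])], ignore_index=True)
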