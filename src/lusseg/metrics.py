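"""Segmentation evaluation metrics.

Pixelwise overlap metrics (Dice, sensitivity/recall, specificity, precision,
F1, IoU) computed from the confusion counts of two binary masks, plus the
symmetric Hausdorff distance between the mask boundaries (Euclidean, in
pixels, on pixel-center coordinates).

Conventions for degenerate denominators: a ratio whose numerator and
denominator are both zero because the relevant structure is absent from both
masks scores 1.0 (perfect agreement); a ratio that is 0/0 while the other
mask disagrees scores 0.0.  The Hausdorff distance is undefined (NaN, with a
flag) when either mask is empty; such images are excluded from aggregation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy.spatial import cKDTree

from .losses import LossConfig, extract_boundary

__all__ = ["ConfusionCounts", "MetricReport", "confusion_counts",
           "overlap_metrics", "hausdorff_distance", "evaluate_pair",
           "aggregate_reports", "METRIC_NAMES"]

METRIC_NAMES = ("dice", "sensitivity", "specificity", "precision", "f1",
                "iou", "hausdorff")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricReport:
    dice: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    iou: float
    hausdorff: float = math.nan       # NaN = undefined (an empty mask)
    degenerate: bool = False          # some ratio used the 0/0 convention

    def as_dict(self) -> dict:
        return asdict(self)


def _as_binary(mask: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(mask)
    vals = np.unique(arr)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError(f"{name} mask must be binary (0/1); got values {vals[:5]}")
    return arr.astype(bool)


def confusion_counts(pred: np.ndarray, target: np.ndarray) -> ConfusionCounts:
    """Exact pixel tallies of TP/FP/FN/TN between two binary masks."""
    p = _as_binary(pred, "pred")
    t = _as_binary(target, "target")
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(np.count_nonzero(~p & ~t))
    return ConfusionCounts(tp, fp, fn, tn)


def _ratio(num: int, den: int, empty_agrees: bool) -> tuple[float, bool]:
    if den == 0:
        return (1.0 if empty_agrees else 0.0), True
    return num / den, False


def overlap_metrics(pred: np.ndarray, target: np.ndarray) -> MetricReport:
    """All ratio metrics from the confusion counts (Hausdorff left NaN)."""
    c = confusion_counts(pred, target)
    tp, fp, fn, tn = c.tp, c.fp, c.fn, c.tn
    degenerate = False

    # "both empty" agreement applies when the structure is absent on both sides
    dice, d1 = _ratio(2 * tp, 2 * tp + fp + fn, empty_agrees=True)
    sens, d2 = _ratio(tp, tp + fn, empty_agrees=fp == 0)
    spec, d3 = _ratio(tn, tn + fp, empty_agrees=fn == 0)
    prec, d4 = _ratio(tp, tp + fp, empty_agrees=fn == 0)
    iou, d5 = _ratio(tp, tp + fp + fn, empty_agrees=True)
    degenerate = d1 or d2 or d3 or d4 or d5
    if prec + sens == 0:
        f1 = 1.0 if (tp + fp + fn) == 0 else 0.0
        degenerate = True
    else:
        f1 = 2 * prec * sens / (prec + sens)
    return MetricReport(dice=dice, sensitivity=sens, specificity=spec,
                        precision=prec, f1=f1, iou=iou, degenerate=degenerate)


def _boundary_points(mask: np.ndarray) -> np.ndarray:
    rim = extract_boundary(mask, LossConfig(boundary_thickness=1))
    return np.argwhere(rim).astype(np.float64)


def hausdorff_distance(pred: np.ndarray, target: np.ndarray,
                       on_boundary: bool = True) -> float:
    """Symmetric Hausdorff distance between two masks, in pixels.

    By default distances are measured between the masks' boundary point sets
    (region minus erosion); ``on_boundary=False`` uses all foreground pixels,
    which coincides for filled regions.  Returns NaN when either mask is
    empty.
    """
    p = _as_binary(pred, "pred")
    t = _as_binary(target, "target")
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    if not p.any() or not t.any():
        warnings.warn("Hausdorff distance undefined for an empty mask",
                      stacklevel=2)
        return math.nan
    if on_boundary:
        a, b = _boundary_points(p), _boundary_points(t)
    else:
        a, b = np.argwhere(p).astype(float), np.argwhere(t).astype(float)
    d_ab = cKDTree(b).query(a, k=1)[0].max()
    d_ba = cKDTree(a).query(b, k=1)[0].max()
    return float(max(d_ab, d_ba))


def evaluate_pair(pred: np.ndarray, target: np.ndarray) -> MetricReport:
    """Full per-image report: overlap metrics plus the Hausdorff distance."""
    report = overlap_metrics(pred, target)
    p = np.asarray(pred) > 0
    t = np.asarray(target) > 0
    if p.any() and t.any():
        report.hausdorff = hausdorff_distance(p.astype(np.uint8),
                                              t.astype(np.uint8))
    return report


def aggregate_reports(reports: list[MetricReport]) -> dict:
    """Unweighted per-image mean and sd; NaN Hausdorff values are skipped."""
    if not reports:
        raise ValueError("no reports to aggregate")
    out: dict = {"n_images": len(reports)}
    for name in METRIC_NAMES:
        vals = np.array([getattr(r, name) for r in reports], dtype=float)
        if name == "hausdorff":
            defined = vals[~np.isnan(vals)]
            out["n_hausdorff_defined"] = int(defined.size)
            vals = defined
        if vals.size:
            out[f"{name}_mean"] = float(vals.mean())
            out[f"{name}_sd"] = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        else:
            out[f"{name}_mean"] = math.nan
            out[f"{name}_sd"] = math.nan
    return out
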