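"""Training loss and evaluation metrics for binary segmentation.

The training objective is the composite Dice + binary-cross-entropy loss;
evaluation uses the overlap family (Dice, IoU, precision, sensitivity)
derived from pixel confusion counts, plus the symmetric 95th-percentile
Hausdorff distance (HD95) for boundary fidelity, and a paired t-test
harness for per-sample score comparisons.

Formulae (TP/FP/FN pixel counts):

    Dice = 2·TP / (2·TP + FP + FN)       IoU  = TP / (TP + FP + FN)
    Precision = TP / (TP + FP)           SE   = TP / (TP + FN)
    HD95(A, B) = max(h95(A, B), h95(B, A))

where h95(A, B) is the 95th percentile, over points of A, of the Euclidean
distance to the nearest point of B.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from . import _tensor as T
from ._tensor import Tensor, as_tensor
from .errors import DegenerateStatisticError, InvalidParameterError, NumericError

__all__ = [
    "ConfusionCounts", "MetricReport",
    "composite_loss", "soft_dice", "confusion", "overlap_metrics",
    "hd95", "paired_t_test", "evaluate_masks", "metric_table",
]


@dataclass
class ConfusionCounts:
    """Pixel-level confusion counts of a binary prediction."""

    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self):
        for name in ("TP", "FP", "FN", "TN"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise InvalidParameterError(f"{name} must be a non-negative integer")
            setattr(self, name, int(v))


@dataclass
class MetricReport:
    """The five per-sample evaluation metrics."""

    dice: float
    iou: float
    precision: float
    sensitivity: float
    hd95: float


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def soft_dice(P: Tensor, Y: Tensor, smooth: float = 1.0) -> Tensor:
    """Differentiable Dice overlap of a probability map against a 0/1 mask."""
    inter = T.tsum(T.mul(P, Y))
    denom = T.tsum(P) + T.tsum(Y)
    return (inter * 2.0 + smooth) / (denom + smooth)


def composite_loss(P, Y, w_dice: float = 1.0, w_bce: float = 1.0,
                   smooth: float = 1.0, eps: float = 1e-7):
    """``w_dice·(1 − softDice(P, Y)) + w_bce·BCE(P, Y)``.

    Accepts numpy arrays (returns a float) or tape tensors (returns a
    differentiable scalar tensor).  P must lie in [0, 1] up to a small
    tolerance; BCE is averaged per pixel with probabilities clipped to
    [eps, 1−eps].
    """
    if w_dice < 0 or w_bce < 0:
        raise InvalidParameterError("loss weights must be non-negative")
    is_tensor = isinstance(P, Tensor)
    Pt = P if is_tensor else as_tensor(np.asarray(P, dtype=np.float64))
    Yt = Y if isinstance(Y, Tensor) else as_tensor(np.asarray(Y, dtype=np.float64))
    if not np.isfinite(Pt.data).all():
        raise NumericError("probability map contains non-finite values")
    if Pt.data.min() < -1e-6 or Pt.data.max() > 1.0 + 1e-6:
        raise NumericError("probabilities outside [0, 1]")
    Pc = T.clip(Pt, eps, 1.0 - eps)
    bce_map = T.neg(T.add(T.mul(Yt, T.log(Pc)),
                          T.mul(1.0 - Yt, T.log(1.0 - Pc))))
    bce = T.tmean(bce_map)
    dice = soft_dice(Pt, Yt, smooth=smooth)
    loss = T.scale(1.0 - dice, w_dice) + T.scale(bce, w_bce)
    return loss if is_tensor else float(loss.data)


# ---------------------------------------------------------------------------
# overlap metrics
# ---------------------------------------------------------------------------

def _as_binary(mask, name: str) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.dtype == bool:
        return mask
    if not np.isin(mask, (0, 1)).all():
        raise InvalidParameterError(f"{name} must be binary")
    return mask.astype(bool)


def confusion(pred_mask, gt_mask) -> ConfusionCounts:
    """Exact pixel confusion counts of two same-shape binary masks."""
    p = _as_binary(pred_mask, "prediction")
    g = _as_binary(gt_mask, "ground truth")
    if p.shape != g.shape:
        raise InvalidParameterError(f"shape mismatch: {p.shape} vs {g.shape}")
    tp = int(np.count_nonzero(p & g))
    fp = int(np.count_nonzero(p & ~g))
    fn = int(np.count_nonzero(~p & g))
    tn = p.size - tp - fp - fn
    return ConfusionCounts(tp, fp, fn, tn)


def overlap_metrics(counts: ConfusionCounts) -> tuple[float, float, float, float]:
    """(Dice, IoU, precision, sensitivity) from confusion counts.

    Degenerate cases: with both masks empty (TP = FP = FN = 0) all four
    metrics are 1; a ratio with an empty denominator while the other mask
    is non-empty is 0.
    """
    tp, fp, fn = counts.TP, counts.FP, counts.FN
    if tp == 0 and fp == 0 and fn == 0:
        return 1.0, 1.0, 1.0, 1.0
    dice = 2.0 * tp / (2.0 * tp + fp + fn)
    iou = tp / (tp + fp + fn)
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    sensitivity = tp / (tp + fn) if tp + fn > 0 else 0.0
    return dice, iou, precision, sensitivity


# ---------------------------------------------------------------------------
# HD95
# ---------------------------------------------------------------------------

def _point_mask(mask: np.ndarray, points: str) -> np.ndarray:
    if points == "foreground":
        return mask
    if points == "boundary":
        return mask & ~ndimage.binary_erosion(mask, border_value=0)
    raise InvalidParameterError(f"unknown point-set mode {points!r}")


def _h95(a: np.ndarray, b: np.ndarray, q: float) -> float:
    dist_to_b = ndimage.distance_transform_edt(~b)
    return float(np.percentile(dist_to_b[a], q))


def hd95(mask_a, mask_b, points: str = "foreground", q: float = 95.0,
         empty_value: float | None = None) -> float:
    """Symmetric 95th-percentile Hausdorff distance in pixel units.

    ``points`` selects the compared sets: all foreground pixels (default)
    or only boundary pixels (foreground minus its erosion).  Percentiles
    interpolate linearly between order statistics.  If either mask is
    empty the distance is undefined; a sentinel (the image diagonal, or
    ``empty_value``) is returned with a warning.
    """
    a = _as_binary(mask_a, "mask_a")
    b = _as_binary(mask_b, "mask_b")
    if a.shape != b.shape:
        raise InvalidParameterError(f"shape mismatch: {a.shape} vs {b.shape}")
    pa = _point_mask(a, points)
    pb = _point_mask(b, points)
    if not pa.any() or not pb.any():
        sentinel = float(np.hypot(*a.shape)) if empty_value is None else empty_value
        warnings.warn("hd95 undefined for an empty mask; returning sentinel",
                      RuntimeWarning, stacklevel=2)
        return sentinel
    return max(_h95(pa, pb, q), _h95(pb, pa, q))


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def paired_t_test(scores_a, scores_b) -> tuple[float, float]:
    """Two-sided paired t-test on per-sample scores.

    Raises :class:`DegenerateStatisticError` when the differences have
    zero variance (the statistic is undefined).
    """
    a = np.asarray(scores_a, dtype=np.float64)
    b = np.asarray(scores_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise InvalidParameterError("score vectors must be 1-D with equal length")
    if a.size < 2:
        raise InvalidParameterError("need at least two paired samples")
    d = a - b
    if np.ptp(d) == 0.0:
        raise DegenerateStatisticError("paired differences have zero variance")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def evaluate_masks(pred_mask, gt_mask, points: str = "foreground") -> MetricReport:
    """All five metrics for one prediction/reference mask pair."""
    dice, iou, precision, se = overlap_metrics(confusion(pred_mask, gt_mask))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        h = hd95(pred_mask, gt_mask, points=points)
    return MetricReport(dice, iou, precision, se, h)


def metric_table(reports: list[MetricReport], sample_ids: list) -> pd.DataFrame:
    """Per-sample metric table plus a ``mean ± sd`` summary row."""
    cols = ["dice", "iou", "precision", "sensitivity", "hd95"]
    df = pd.DataFrame([{c: getattr(r, c) for c in cols} for r in reports],
                      index=pd.Index(sample_ids, name="sample_id"))
    mean, sd = df.mean(), df.std(ddof=1)
    summary = pd.DataFrame(
        {c: [f"{mean[c]:.4f} (± {0.0 if np.isnan(sd[c]) else sd[c]:.4f})"]
         for c in cols},
        index=pd.Index(["mean ± sd"], name="sample_id"))
    return pd.concat([df.astype(object), summary])
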