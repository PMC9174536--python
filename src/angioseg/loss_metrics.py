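"""Training objective and pixel-level evaluation metrics.

The objective combines a class-weighted cross-entropy with a Dice term,

    L = L_WCE + beta * L_Dice,
    L_WCE = -mean( alpha * w * y * log(p) + (1 - w) * (1 - y) * log(1 - p) ),
    w = 1 - sum(y) / (H * W)   (per image),
    L_Dice = 1 - (2 * sum(y p) + eps) / (sum y + sum p + eps),

where ``w`` counteracts the severe vessel/background imbalance of angiograms
(vessels are a few percent of the pixels) and ``alpha`` (default 0.2)
fine-tunes the positive term.  ``beta`` defaults to 0.01.

Evaluation reports confusion counts, sensitivity SE = TP/(TP+FN),
specificity SP = TN/(TN+FP), accuracy ACC = (TP+TN)/total, and the area
under the ROC curve over pixels pooled across the whole test set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autograd import Tensor, clip_ste

__all__ = [
    "LossParams",
    "ConfusionCounts",
    "MetricsReport",
    "class_weight",
    "weighted_ce",
    "dice_loss",
    "total_loss",
    "dice_coefficient",
    "confusion",
    "se_sp_acc",
    "roc_auc",
    "evaluate_predictions",
]


@dataclass(frozen=True)
class LossParams:
    alpha_ce: float = 0.2
    beta: float = 0.01
    smooth_eps: float = 1.0
    clip_eps: float = 1e-7

    def __post_init__(self):
        if self.alpha_ce <= 0:
            raise ValueError("alpha_ce must be positive")
        if self.beta < 0:
            raise ValueError("beta must be non-negative")


def _as_batch(y) -> np.ndarray:
    """Normalize a mask / prediction to (B, 1, H, W) float32."""
    y = np.asarray(y, dtype=np.float32)
    if y.ndim == 2:
        y = y[None, None]
    elif y.ndim == 3:
        y = y[:, None]
    elif y.ndim != 4:
        raise ValueError(f"expected 2-D, 3-D or 4-D raster, got {y.shape}")
    return y


def class_weight(y) -> np.ndarray:
    """Background weight w = 1 - vessel fraction, per image."""
    y = _as_batch(y)
    if y[0, 0].size == 0:
        raise ValueError("empty mask raster")
    w = 1.0 - y.mean(axis=(1, 2, 3))
    return w.astype(np.float32)


def _prep(y, p):
    yb = _as_batch(y)
    if isinstance(p, Tensor):
        if p.shape != yb.shape:
            p = p.reshape(yb.shape)
    else:
        p = Tensor(_as_batch(p))
    if tuple(p.shape) != yb.shape:
        raise ValueError(f"shape mismatch: mask {yb.shape} vs prediction {p.shape}")
    return yb, p


def weighted_ce(y, p, params: LossParams = LossParams()) -> Tensor:
    """Class-weighted binary cross-entropy, mean over all pixels."""
    yb, p = _prep(y, p)
    w = class_weight(yb).reshape(-1, 1, 1, 1)
    eps = params.clip_eps
    pc = clip_ste(p, eps, 1.0 - eps)
    pos = (params.alpha_ce * w * yb) * pc.log()
    neg = ((1.0 - w) * (1.0 - yb)) * (1.0 - pc).log()
    return -(pos + neg).mean()


def dice_loss(y, p, params: LossParams = LossParams()) -> Tensor:
    """1 - Dice overlap between probabilities and the binary mask."""
    yb, p = _prep(y, p)
    eps = params.smooth_eps
    inter = (p * yb).sum(axis=(1, 2, 3))
    denom = p.sum(axis=(1, 2, 3)) + yb.sum(axis=(1, 2, 3))
    dice = (2.0 * inter + eps) / (denom + eps)
    return (1.0 - dice).mean()


def total_loss(y, p, params: LossParams = LossParams()) -> Tensor:
    """Weighted cross-entropy plus ``beta`` times the Dice loss."""
    return weighted_ce(y, p, params) + params.beta * dice_loss(y, p, params)


def dice_coefficient(y, p, threshold: float = 0.5) -> float:
    """Hard Dice overlap of the thresholded prediction (an evaluation aid)."""
    yb = _as_batch(y)
    pb = _as_batch(p.data if isinstance(p, Tensor) else p) >= threshold
    inter = float((pb * yb).sum())
    denom = float(pb.sum() + yb.sum())
    return 2.0 * inter / denom if denom else 1.0


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn)


@dataclass(frozen=True)
class MetricsReport:
    sensitivity: float
    specificity: float
    accuracy: float
    auc: float
    counts: ConfusionCounts
    roc_points: tuple
    undefined: frozenset = frozenset()

    def to_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "auc": self.auc,
            "counts": {"tp": self.counts.tp, "tn": self.counts.tn,
                       "fp": self.counts.fp, "fn": self.counts.fn},
            "undefined": sorted(self.undefined),
        }


def confusion(y, p, threshold: float = 0.5) -> ConfusionCounts:
    """Pixel-wise confusion counts at ``p >= threshold``."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    yb = _as_batch(y).astype(bool)
    pb = _as_batch(p.data if isinstance(p, Tensor) else p) >= threshold
    tp = int((pb & yb).sum())
    tn = int((~pb & ~yb).sum())
    fp = int((pb & ~yb).sum())
    fn = int((~pb & yb).sum())
    return ConfusionCounts(tp, tn, fp, fn)


def se_sp_acc(c: ConfusionCounts):
    """(sensitivity, specificity, accuracy); NaN flags a zero denominator."""
    se = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else float("nan")
    sp = c.tn / (c.tn + c.fp) if (c.tn + c.fp) else float("nan")
    acc = (c.tp + c.tn) / c.total if c.total else float("nan")
    return se, sp, acc


def roc_auc(y, scores):
    """ROC over all unique thresholds on pooled pixels, AUC by trapezoid.

    The trapezoidal area equals the pairwise rank statistic
    P(score_vessel > score_background) + 0.5 * P(tie).  Returns
    ``(roc_points, auc)``; a single-class pool yields ``auc = nan`` and an
    empty curve.
    """
    yf = np.concatenate([np.asarray(m).ravel() for m in np.atleast_1d(y)]) \
        if isinstance(y, (list, tuple)) else np.asarray(y).ravel()
    sf = np.concatenate([np.asarray(s).ravel() for s in np.atleast_1d(scores)]) \
        if isinstance(scores, (list, tuple)) else np.asarray(scores).ravel()
    if yf.shape != sf.shape:
        raise ValueError("label and score pools differ in size")
    P = int(yf.sum())
    N = yf.size - P
    if P == 0 or N == 0:
        return ((), float("nan"))
    order = np.argsort(-sf, kind="stable")
    ys = yf[order]
    ss = sf[order]
    tps = np.cumsum(ys)
    fps = np.cumsum(1 - ys)
    # keep one operating point per unique threshold (the last of each tie run)
    last = np.r_[ss[1:] != ss[:-1], True]
    tpr = np.r_[0.0, tps[last] / P]
    fpr = np.r_[0.0, fps[last] / N]
    auc = float(np.trapezoid(tpr, fpr))
    points = tuple(zip(fpr.tolist(), tpr.tolist()))
    return points, auc


def evaluate_predictions(masks, probs, threshold: float = 0.5) -> MetricsReport:
    """Full metrics report over a set of predictions, pixels pooled."""
    masks = list(masks) if isinstance(masks, (list, tuple)) else [masks]
    probs = list(probs) if isinstance(probs, (list, tuple)) else [probs]
    if len(masks) != len(probs):
        raise ValueError("mask and prediction sets differ in length")
    counts = ConfusionCounts(0, 0, 0, 0)
    for m, p in zip(masks, probs):
        counts = counts + confusion(m, p, threshold)
    se, sp, acc = se_sp_acc(counts)
    roc, auc = roc_auc([np.asarray(m) for m in masks],
                       [np.asarray(p.data if isinstance(p, Tensor) else p)
                        for p in probs])
    undefined = frozenset(
        name for name, v in
        (("sensitivity", se), ("specificity", sp), ("accuracy", acc),
         ("auc", auc)) if np.isnan(v))
    return MetricsReport(se, sp, acc, auc, counts, roc, undefined)
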