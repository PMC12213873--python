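"""Training objective and evaluation metrics for binary segmentation.

The objective is the weighted sum

    L_total = alpha * L_BCE + beta * L_Dice,      alpha = beta = 1,

with BCE evaluated in the numerically stable logit form and Dice loss
1 - (2*sum(p*g) + eps) / (sum(p) + sum(g) + eps), eps = 1.

Evaluation reports Dice, mIoU, Precision and Recall from the binary
contingency counts. mIoU follows the 2-class semantic convention (mean
of foreground and background IoU); foreground-only IoU is reported
alongside for transparency. Metric edge case: an empty prediction
against an empty ground truth scores 1.0 on every overlap metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tensor import Tensor, as_tensor

__all__ = ["LossWeights", "dice_loss", "bce_loss", "bce_with_logits",
           "total_loss", "MetricsReport", "seg_metrics", "aggregate_metrics"]

_CLAMP = 1e-7


@dataclass(frozen=True)
class LossWeights:
    alpha: float = 1.0
    beta: float = 1.0
    epsilon: float = 1.0

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("loss weights must be non-negative")
        if self.epsilon <= 0:
            raise ValueError("dice smoothing epsilon must be positive")


def _check_pair(p, g):
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")


def dice_loss(p, g, epsilon: float = 1.0):
    """Soft Dice loss on probabilities in [0,1] against a binary mask."""
    p, g = as_tensor(p), as_tensor(np.asarray(g, dtype=np.float64)
                                   if not isinstance(g, Tensor) else g)
    _check_pair(p, g)
    inter = (p * g).sum()
    denom = p.sum() + g.sum()
    return 1.0 - (2.0 * inter + epsilon) / (denom + epsilon)


def bce_loss(p, g):
    """Mean binary cross-entropy from probabilities (clamped to (0,1))."""
    p, g = as_tensor(p), as_tensor(g)
    _check_pair(p, g)
    pc = Tensor(np.clip(p.data, _CLAMP, 1.0 - _CLAMP)) if not p.requires_grad else p
    if p.requires_grad:
        # keep the graph: clamp via a detached correction
        lo = np.clip(p.data, _CLAMP, 1.0 - _CLAMP) - p.data
        pc = p + Tensor(lo)
    return -(g * pc.log() + (1.0 - g) * (1.0 - pc).log()).mean()


def bce_with_logits(logits, g):
    """Stable BCE from logits: mean(softplus(z) - g*z)."""
    z, g = as_tensor(logits), as_tensor(g)
    _check_pair(z, g)
    return (z.softplus() - g * z).mean()


def total_loss(p, g, weights: LossWeights = LossWeights(), from_logits: bool = False):
    """alpha*BCE + beta*Dice. With ``from_logits`` the input is a logit map."""
    if from_logits:
        p_t = as_tensor(p)
        bce = bce_with_logits(p_t, g)
        dice = dice_loss(p_t.sigmoid(), g, weights.epsilon)
    else:
        bce = bce_loss(p, g)
        dice = dice_loss(p, g, weights.epsilon)
    return weights.alpha * bce + weights.beta * dice


@dataclass
class MetricsReport:
    tp: int
    fp: int
    fn: int
    tn: int
    dice: float
    miou: float
    iou_fg: float
    precision: float
    recall: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("tp", "fp", "fn", "tn", "dice", "miou", "iou_fg",
                 "precision", "recall")}


def _safe(num: float, den: float, empty_value: float) -> float:
    return empty_value if den == 0 else num / den


def seg_metrics(pred_mask, g) -> MetricsReport:
    """Contingency counts and the four overlap metrics for binary masks."""
    p = np.asarray(pred_mask).astype(bool)
    t = np.asarray(g).astype(bool)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    tp = int(np.sum(p & t))
    fp = int(np.sum(p & ~t))
    fn = int(np.sum(~p & t))
    tn = int(np.sum(~p & ~t))
    dice = _safe(2 * tp, 2 * tp + fp + fn, 1.0)
    iou_fg = _safe(tp, tp + fp + fn, 1.0)
    iou_bg = _safe(tn, tn + fp + fn, 1.0)
    return MetricsReport(
        tp=tp, fp=fp, fn=fn, tn=tn, dice=dice,
        miou=0.5 * (iou_fg + iou_bg), iou_fg=iou_fg,
        precision=_safe(tp, tp + fp, 1.0), recall=_safe(tp, tp + fn, 1.0))


def aggregate_metrics(reports: list[MetricsReport]) -> dict:
    """Dataset-level mean of the per-image metrics."""
    if not reports:
        raise ValueError("no reports to aggregate")
    keys = ("dice", "miou", "iou_fg", "precision", "recall")
    return {k: float(np.mean([getattr(r, k) for r in reports])) for k in keys}
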