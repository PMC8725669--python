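"""Segmentation losses and overlap metrics.

Soft two-class dice loss, cross-entropy, focal loss and their weighted sum
("total loss"), plus Mean-IoU and Mean-F over image sets.  Losses are means
over pixels so values are image-size invariant.  Notation: ``L_FP`` is the
predicted foreground probability, ``L_BP = 1 - L_FP`` the predicted
background, ``L_FR``/``L_BR`` the real foreground/background indicator
masks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LossParams",
    "dice_loss",
    "cross_entropy_loss",
    "focal_loss",
    "total_loss",
    "mean_iou",
    "mean_fscore",
]

_CLIP = 1e-7


@dataclass(frozen=True)
class LossParams:
    """eps: smoothing added to numerators/denominators; gamma: focal
    modulation exponent; w_t: total-loss weight on the focal term; mode:
    "standard" two-class soft dice, or "literal" for an unhalved
    variant seen in the literature (does not vanish at perfect overlap)."""

    eps: float = 1e-6
    gamma: float = 2.0
    w_t: float = 1.0
    mode: str = "standard"

    def __post_init__(self):
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if self.gamma < 0 or self.w_t < 0:
            raise ValueError("gamma and w_t must be non-negative")
        if self.mode not in ("standard", "literal"):
            raise ValueError(f"unknown mode {self.mode!r}")


def _check_pair(pred, truth):
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    if pred.min() < 0 or pred.max() > 1:
        raise ValueError("predicted probabilities must lie in [0, 1]")
    if not np.all(np.isin(np.unique(truth), (0.0, 1.0))):
        raise ValueError("truth mask must be binary")
    return pred, truth


def dice_loss(pred, truth, p: LossParams = LossParams()) -> float:
    """Two-class soft dice loss.

    standard mode:
        1 - 1/2 * [ (2*sum(L_FP*L_FR)+eps)/(sum(L_FP)+sum(L_FR)+eps)
                  + (2*sum(L_BP*L_BR)+eps)/(sum(L_BP)+sum(L_BR)+eps) ]
    literal mode keeps the unhalved per-class fractions without the
    factor 2 and with the background denominator sum(2 - L_FP + L_FR) + eps.
    """
    fp, fr = _check_pair(pred, truth)
    bp, br = 1.0 - fp, 1.0 - fr
    e = p.eps
    if p.mode == "standard":
        f1 = (2.0 * (fp * fr).sum() + e) / (fp.sum() + fr.sum() + e)
        f2 = (2.0 * (bp * br).sum() + e) / (bp.sum() + br.sum() + e)
        return float(1.0 - 0.5 * (f1 + f2))
    f1 = ((fp * fr).sum() + e) / (fp.sum() + fr.sum() + e)
    f2 = ((bp * br).sum() + e) / ((2.0 - fp + fr).sum() + e)
    return float(1.0 - f1 - f2)


def focal_loss(pred, truth, p: LossParams = LossParams()) -> float:
    """Mean over pixels of -(1 - p_t)^gamma * log(p_t), with p_t the
    predicted probability of the true class.  gamma = 0 reduces exactly to
    binary cross-entropy."""
    fp, fr = _check_pair(pred, truth)
    fp = np.clip(fp, _CLIP, 1.0 - _CLIP)
    p_t = np.where(fr == 1.0, fp, 1.0 - fp)
    return float(np.mean(-((1.0 - p_t) ** p.gamma) * np.log(p_t)))


def cross_entropy_loss(pred, truth, p: LossParams = LossParams()) -> float:
    """Mean binary cross-entropy (the gamma = 0 focal loss)."""
    return focal_loss(pred, truth, LossParams(eps=p.eps, gamma=0.0,
                                              w_t=p.w_t, mode=p.mode))


def total_loss(pred, truth, p: LossParams = LossParams()) -> float:
    """dice_loss + w_t * focal_loss."""
    return dice_loss(pred, truth, p) + p.w_t * focal_loss(pred, truth, p)


def _binary_lists(preds, truths):
    if len(preds) == 0 or len(preds) != len(truths):
        raise ValueError("need equal-length, non-empty mask lists")
    out = []
    for pr, tr in zip(preds, truths):
        pr = np.asarray(pr).astype(bool)
        tr = np.asarray(tr).astype(bool)
        if pr.shape != tr.shape:
            raise ValueError("mask shape mismatch")
        out.append((pr, tr))
    return out


def mean_iou(preds, truths) -> float:
    """Mean per-image foreground intersection-over-union; an image where
    prediction and truth are both empty counts as IoU 1."""
    ious = []
    for pr, tr in _binary_lists(preds, truths):
        union = np.logical_or(pr, tr).sum()
        ious.append(1.0 if union == 0 else np.logical_and(pr, tr).sum() / union)
    return float(np.mean(ious))


def mean_fscore(preds, truths, w_t: float = 1.0) -> float:
    """Mean per-image F_beta with beta^2 = w_t:
    (1 + w_t) * P * R / (w_t * P + R).  Empty prediction and truth -> 1;
    empty prediction against non-empty truth -> 0."""
    scores = []
    for pr, tr in _binary_lists(preds, truths):
        tp = np.logical_and(pr, tr).sum()
        if pr.sum() == 0 and tr.sum() == 0:
            scores.append(1.0)
            continue
        if tp == 0:
            scores.append(0.0)
            continue
        prec = tp / pr.sum()
        rec = tp / tr.sum()
        scores.append((1.0 + w_t) * prec * rec / (w_t * prec + rec))
    return float(np.mean(scores))
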