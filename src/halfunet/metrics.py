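"""Segmentation evaluation: Dice coefficient, sensitivity, specificity,
and the soft Dice loss used for training.

Predictions may be probability maps in [0, 1] (thresholded at 0.5 by
default for the hard metrics) or already-binary masks; ground truth must
be strictly binary. For an empty denominator, sensitivity and specificity
return ``nan`` as an explicit undefined marker (aggregation skips it);
Dice of two empty masks is defined as 1.0.
"""

from __future__ import annotations

import numpy as np

from .engine import ShapeError

__all__ = ["dice", "sensitivity", "specificity", "dice_loss", "dice_loss_grad",
           "confusion_counts", "UNDEFINED"]

UNDEFINED = float("nan")


def _binarize(a, threshold):
    a = np.asarray(a)
    if a.dtype == bool:
        return a
    return a >= threshold


def _check(pred, truth):
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ShapeError(f"mask shapes differ: {pred.shape} vs {truth.shape}")
    tvals = np.unique(truth)
    if not np.all(np.isin(tvals, (0, 1))):
        raise ValueError(f"ground truth must be binary, found values {tvals[:5]}")
    return pred, truth


def confusion_counts(pred, truth, threshold=0.5):
    """(TP, FP, TN, FN) pixel counts after thresholding the prediction."""
    pred, truth = _check(pred, truth)
    p = _binarize(pred, threshold)
    m = truth.astype(bool)
    tp = int(np.count_nonzero(p & m))
    fp = int(np.count_nonzero(p & ~m))
    tn = int(np.count_nonzero(~p & ~m))
    fn = int(np.count_nonzero(~p & m))
    return tp, fp, tn, fn


def dice(pred, truth, threshold=0.5) -> float:
    """2|P∩M| / (|P|+|M|); 1.0 when both masks are empty."""
    tp, fp, tn, fn = confusion_counts(pred, truth, threshold)
    denom = 2 * tp + fp + fn
    if denom == 0:
        return 1.0
    return 2.0 * tp / denom


def sensitivity(pred, truth, threshold=0.5) -> float:
    """TP / (ground-truth positives); nan when there are no positives."""
    tp, fp, tn, fn = confusion_counts(pred, truth, threshold)
    pos = tp + fn
    return UNDEFINED if pos == 0 else tp / pos


def specificity(pred, truth, threshold=0.5) -> float:
    """TN / (ground-truth negatives); nan when there are no negatives."""
    tp, fp, tn, fn = confusion_counts(pred, truth, threshold)
    neg = tn + fp
    return UNDEFINED if neg == 0 else tn / neg


# ---------------------------------------------------------------------------
# soft Dice loss


def dice_loss(probs, truth, eps: float = 1.0) -> float:
    """1 - soft Dice on raw probabilities, smoothed by ``eps`` in numerator
    and denominator. Accepts a single map or a batch (leading axis);
    batches are averaged per image."""
    loss, _ = dice_loss_grad(probs, truth, eps)
    return loss


def dice_loss_grad(probs, truth, eps: float = 1.0):
    """Soft Dice loss and its gradient with respect to the probabilities.

    Per image i: L_i = 1 - (2 Σ p g + eps) / (Σ p + Σ g + eps); the result
    is the mean over the batch, so the gradient carries a 1/N factor.
    """
    p = np.asarray(probs)
    if not np.issubdtype(p.dtype, np.floating):
        p = p.astype(np.float32)
    g = np.asarray(truth, dtype=p.dtype)
    if p.shape != g.shape:
        raise ShapeError(f"shapes differ: {p.shape} vs {g.shape}")
    squeeze = p.ndim == 2
    if squeeze:
        p, g = p[None], g[None]
    n = p.shape[0]
    axes = tuple(range(1, p.ndim))
    inter = (p * g).sum(axis=axes)
    sums = p.sum(axis=axes) + g.sum(axis=axes)
    num = 2.0 * inter + eps
    den = sums + eps
    loss = float(np.mean(1.0 - num / den))
    grad = -(2.0 * g * den.reshape((-1,) + (1,) * (p.ndim - 1))
             - num.reshape((-1,) + (1,) * (p.ndim - 1))) \
        / (den.reshape((-1,) + (1,) * (p.ndim - 1)) ** 2) / n
    if squeeze:
        grad = grad[0]
    return loss, grad.astype(p.dtype, copy=False)
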