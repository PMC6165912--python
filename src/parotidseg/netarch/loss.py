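"""Soft Dice loss for class-imbalanced binary segmentation."""

from __future__ import annotations

import numpy as np

__all__ = ["soft_dice_loss", "soft_dice_grad", "softmax_probs"]

EPS = 1e-5


def soft_dice_loss(pred: np.ndarray, target: np.ndarray, eps: float = EPS) -> float:
    """``1 - (2*sum(p*t) + eps) / (sum(p) + sum(t) + eps)``.

    ``pred`` holds foreground probabilities in [0, 1]; ``target`` is
    binary; both must have identical extents.  The smoothing term ``eps``
    guards empty masks, so the loss is defined (and ~0) when both are
    empty.
    """
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"extent mismatch: {pred.shape} vs {target.shape}")
    if pred.min() < -1e-6 or pred.max() > 1 + 1e-6:
        raise ValueError("predictions must lie in [0, 1]")
    inter = float((pred * target).sum())
    total = float(pred.sum() + target.sum())
    return float(1.0 - (2.0 * inter + eps) / (total + eps))


def soft_dice_grad(pred: np.ndarray, target: np.ndarray, eps: float = EPS) -> np.ndarray:
    """Gradient of :func:`soft_dice_loss` with respect to ``pred``."""
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    inter = (pred * target).sum()
    total = pred.sum() + target.sum()
    denom = total + eps
    # d/dp_i [ -(2I+eps)/(S+eps) ] = -(2 t_i (S+eps) - (2I+eps)) / (S+eps)^2
    g = -(2.0 * target * denom - (2.0 * inter + eps)) / (denom * denom)
    return g.astype(np.float32)


def softmax_probs(logits: np.ndarray) -> np.ndarray:
    """Stable softmax over the channel axis (axis 1)."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)
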