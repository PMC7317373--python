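"""Loss functions operating on network logits; each returns (loss, dlogits)."""

from __future__ import annotations

import numpy as np

from .layers import DTYPE


def _softmax(z: np.ndarray, axis: int) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Multinomial cross-entropy.

    ``logits`` is (N, K) with integer ``labels`` (N,), or (N, K, H, W) with
    labels (N, H, W) for per-pixel classification.
    """
    if logits.ndim == 2:
        p = _softmax(logits, axis=1)
        n = logits.shape[0]
        ll = -np.log(np.maximum(p[np.arange(n), labels], 1e-12))
        grad = p.copy()
        grad[np.arange(n), labels] -= 1.0
        return float(ll.mean()), (grad / n).astype(DTYPE)
    p = _softmax(logits, axis=1)
    n, k, h, w = logits.shape
    onehot = np.zeros_like(p)
    ii, rr, cc = np.meshgrid(np.arange(n), np.arange(h), np.arange(w), indexing="ij")
    onehot[ii, labels, rr, cc] = 1.0
    ll = -(onehot * np.log(np.maximum(p, 1e-12))).sum(axis=1)
    grad = (p - onehot) / (n * h * w)
    return float(ll.mean()), grad.astype(DTYPE)


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    diff = pred - target
    return float(np.mean(diff**2)), (2.0 * diff / diff.size).astype(DTYPE)


def soft_dice_loss(logits: np.ndarray, target: np.ndarray, eps: float = 1e-6) -> tuple[float, np.ndarray]:
    """1 - soft Dice on sigmoid probabilities; reduces to 1 - DSC on hard masks.

    ``logits``/``target`` are (N, 1, H, W); the Dice ratio is computed per
    sample and averaged.
    """
    p = 1.0 / (1.0 + np.exp(-logits))
    t = target.astype(np.float64)
    axes = (1, 2, 3)
    inter = (p * t).sum(axis=axes)
    denom = p.sum(axes) + t.sum(axes)
    dice = (2.0 * inter + eps) / (denom + eps)
    loss = float(np.mean(1.0 - dice))
    # d dice / d p = (2 t (denom+eps) - (2 inter+eps)) / (denom+eps)^2
    ddice_dp = (2.0 * t * (denom + eps)[:, None, None, None] - (2.0 * inter + eps)[:, None, None, None]) / (
        (denom + eps) ** 2
    )[:, None, None, None]
    dp = -ddice_dp / logits.shape[0]
    grad = dp * p * (1.0 - p)
    return loss, grad.astype(DTYPE)
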