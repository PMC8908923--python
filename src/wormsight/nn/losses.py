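"""Training losses with analytic gradients with respect to the output probabilities."""

from __future__ import annotations

import numpy as np

DICE_EPS = 1e-6


def dice_coefficient(pred, truth, eps=DICE_EPS):
    """Smoothed Soerensen-Dice coefficient.

    ``pred`` and ``truth`` are ``(N, H, W, C)`` (or ``(N, H, W)``); the
    coefficient is computed per sample and channel over the spatial axes and
    averaged.
    """
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    if pred.ndim == 3:
        pred, truth = pred[..., None], truth[..., None]
    inter = (pred * truth).sum(axis=(1, 2))
    sums = pred.sum(axis=(1, 2)) + truth.sum(axis=(1, 2))
    return float(((2.0 * inter + eps) / (sums + eps)).mean())


def dice_loss_grad(pred, truth, eps=DICE_EPS):
    """Dice loss (1 - smoothed Dice) and its gradient w.r.t. ``pred``.

    Per-sample, per-channel Dice over the spatial axes, averaged over samples
    and channels.
    """
    squeeze = pred.ndim == 3
    if squeeze:
        pred, truth = pred[..., None], truth[..., None]
    inter = (pred * truth).sum(axis=(1, 2), keepdims=True)
    sums = pred.sum(axis=(1, 2), keepdims=True) + truth.sum(axis=(1, 2), keepdims=True)
    num = 2.0 * inter + eps
    den = sums + eps
    n_terms = pred.shape[0] * pred.shape[-1]
    loss = float((1.0 - num / den).mean(axis=(1, 2)).sum() / n_terms)
    # d/dp [ -(2*sum(p*t)+eps)/(sum(p)+sum(t)+eps) ] = -(2*t*den - num)/den^2
    dpred = (-(2.0 * truth * den - num) / (den * den) / n_terms).astype(pred.dtype)
    if squeeze:
        dpred = dpred[..., 0]
    return loss, dpred


def cross_entropy(probs, onehot, clip=1e-12):
    """Mean categorical cross-entropy and its gradient w.r.t. ``probs``.

    With a two-way softmax head this is exactly the binary cross-entropy of
    the positive-class probability.
    """
    n = probs.shape[0]
    p = np.clip(probs, clip, 1.0)
    loss = float(-(onehot * np.log(p)).sum() / n)
    dprobs = (-(onehot / p) / n).astype(probs.dtype)
    return loss, dprobs
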