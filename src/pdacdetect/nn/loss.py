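"""Compound soft-Dice + cross-entropy segmentation loss.

Both terms are differentiated analytically with respect to the logits so
the network backward pass starts from a single gradient grid.  The Dice
term uses the usual smoothed formulation ``(2*sum(p*t)+s)/(sum p + sum t + s)``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["dice_ce_loss"]

_SMOOTH = 1.0


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def dice_ce_loss(logits: np.ndarray, target: np.ndarray, head: str = "sigmoid"):
    """Loss value and gradient w.r.t. logits.

    ``logits``: (C, X, Y, Z).  For the sigmoid head the target is a binary
    grid per channel; for the softmax head the target is an integer class
    grid of spatial shape.  Returns ``(loss, dlogits)``.
    """
    if head == "sigmoid":
        t = np.asarray(target, dtype=float)
        if t.ndim == 3:
            t = t[None]
        p = _sigmoid(logits)
        n = logits.size
        # binary cross-entropy, numerically stable in the logits
        ce = np.mean(np.maximum(logits, 0) - logits * t + np.log1p(np.exp(-np.abs(logits))))
        num = 2.0 * (p * t).sum() + _SMOOTH
        den = p.sum() + t.sum() + _SMOOTH
        dice = num / den
        dce = (p - t) / n
        ddice_dp = (2.0 * t * den - num) / den**2
        dlogits = dce - ddice_dp * p * (1.0 - p)
        return float(ce + 1.0 - dice), dlogits

    # softmax head: target is an integer class grid
    t = np.asarray(target)
    C = logits.shape[0]
    z = logits - logits.max(axis=0, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=0, keepdims=True)
    onehot = np.stack([(t == c) for c in range(C)]).astype(float)
    nvox = t.size
    ce = -np.mean(np.log(np.clip((p * onehot).sum(axis=0), 1e-12, None)))
    dce = (p - onehot) / nvox

    # mean soft Dice over the non-background classes (class 0 = background)
    nfg = max(C - 1, 1)
    dice_sum = 0.0
    gp = np.zeros_like(p)
    for c in range(1, C):
        num = 2.0 * (p[c] * onehot[c]).sum() + _SMOOTH
        den = p[c].sum() + onehot[c].sum() + _SMOOTH
        dice_sum += num / den
        gp[c] += -(2.0 * onehot[c] * den - num) / den**2 / nfg
    mean_dice = dice_sum / nfg
    # chain through softmax: dz_c = p_c * (g_c - sum_k p_k g_k)
    ddice = p * (gp - (p * gp).sum(axis=0, keepdims=True))
    return float(ce + 1.0 - mean_dice), dce + ddice
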