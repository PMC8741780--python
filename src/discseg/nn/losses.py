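"""Pixel-wise losses for binary segmentation."""

from __future__ import annotations

import numpy as np

BCE_EPS = 1e-7


def bce_loss(prediction: np.ndarray, target: np.ndarray, eps: float = BCE_EPS):
    """Mean per-pixel binary cross-entropy with its gradient.

    ``-[t ln p + (1 - t) ln(1 - p)]`` averaged over all pixels, with the
    probabilities clipped to ``[eps, 1 - eps]`` before the logarithms.
    Returns ``(loss, dloss/dprediction)``; the gradient is zero wherever
    the clip is active.

    Raises ``ValueError`` on shape mismatch.
    """
    p = np.asarray(prediction, dtype=np.float64)
    t = np.asarray(target, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError(f"prediction shape {p.shape} != target shape {t.shape}")
    pc = np.clip(p, eps, 1.0 - eps)
    n = p.size
    loss = -np.sum(t * np.log(pc) + (1.0 - t) * np.log1p(-pc)) / n
    grad = np.where(
        (p > eps) & (p < 1.0 - eps),
        (pc - t) / (pc * (1.0 - pc)) / n,
        0.0,
    ).astype(np.float32)
    return float(loss), grad


def dice_loss(prediction: np.ndarray, target: np.ndarray, smooth: float = 1.0):
    """Soft Dice loss ``1 - (2 sum(pt) + s) / (sum(p) + sum(t) + s)`` with gradient.

    Available as an alternative training objective; not the default, so the
    Dice evaluation metric stays independent of the objective optimized.
    """
    p = np.asarray(prediction, dtype=np.float64)
    t = np.asarray(target, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError(f"prediction shape {p.shape} != target shape {t.shape}")
    inter = np.sum(p * t)
    denom = np.sum(p) + np.sum(t) + smooth
    dice = (2.0 * inter + smooth) / denom
    grad = -(2.0 * t * denom - (2.0 * inter + smooth)) / denom**2
    return float(1.0 - dice), grad.astype(np.float32)


LOSSES = {"bce": bce_loss, "dice": dice_loss}
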