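"""Segmentation losses: cross-entropy, soft Dice, and active contour.

Each loss takes a probability map ``pred`` and a binary ground-truth mask
``truth`` (same shape, any leading batch dimensions) and returns
``(value, d(value)/d(pred))``.  The active-contour loss combines a length
term — the total finite-difference gradient magnitude of the prediction,
which penalizes ragged, noisy boundaries — and a region term that drives
pixel probabilities toward the inside/outside intensities c1 = 1, c2 = 0.
"""

from __future__ import annotations

import numpy as np

from ..errors import ParameterError

__all__ = ["ce_loss", "dice_loss", "active_contour_loss", "loss"]

_EPS = 1e-7


def _check(pred: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape:
        raise ParameterError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    if np.isnan(pred).any():
        raise FloatingPointError("NaN in predicted probability map")
    return pred, truth


def ce_loss(pred: np.ndarray, truth: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy per pixel."""
    pred, truth = _check(pred, truth)
    p = np.clip(pred, _EPS, 1.0 - _EPS)
    n = p.size
    value = float(-np.mean(truth * np.log(p) + (1.0 - truth) * np.log1p(-p)))
    grad = (p - truth) / (p * (1.0 - p)) / n
    return value, grad


def dice_loss(pred: np.ndarray, truth: np.ndarray,
              eps: float = 1e-6) -> tuple[float, np.ndarray]:
    """Soft Dice loss, 1 - (2*sum(p*t) + eps) / (sum(p) + sum(t) + eps)."""
    pred, truth = _check(pred, truth)
    inter = float(np.sum(pred * truth))
    denom = float(np.sum(pred) + np.sum(truth)) + eps
    value = 1.0 - (2.0 * inter + eps) / denom
    grad = -(2.0 * truth * denom - (2.0 * inter + eps)) / denom**2
    return value, grad


def active_contour_loss(pred: np.ndarray, truth: np.ndarray,
                        length_weight: float = 1.0,
                        region_weight: float = 1.0,
                        eps: float = 1e-8) -> tuple[float, np.ndarray]:
    """Length + region active-contour loss (c1 = 1, c2 = 0), per pixel.

    Length term: mean of sqrt((dp/dr)^2 + (dp/dc)^2 + eps) over pixels, with
    forward differences on the last two axes.  Region term: mean of
    p*(t-1)^2 + (1-p)*t^2.  Both terms are normalized per pixel so the
    weights are resolution-independent.
    """
    pred, truth = _check(pred, truth)
    n = pred.size
    dr = np.diff(pred, axis=-2)
    dc = np.diff(pred, axis=-1)
    dr2 = np.zeros_like(pred)
    dc2 = np.zeros_like(pred)
    dr2[..., :-1, :] = dr
    dc2[..., :, :-1] = dc
    mag = np.sqrt(dr2**2 + dc2**2 + eps)
    length = float(np.sum(mag)) / n
    # Region: c1 = 1 inside, c2 = 0 outside.
    region_map = pred * (truth - 1.0) ** 2 + (1.0 - pred) * truth**2
    region = float(np.sum(region_map)) / n

    grad = np.zeros_like(pred)
    # d(length)/dp: divergence (adjoint of the forward differences).
    gr = dr2 / mag
    gc = dc2 / mag
    grad[..., :-1, :] -= gr[..., :-1, :]
    grad[..., 1:, :] += gr[..., :-1, :]
    grad[..., :, :-1] -= gc[..., :, :-1]
    grad[..., :, 1:] += gc[..., :, :-1]
    grad *= length_weight / n
    grad += region_weight * ((truth - 1.0) ** 2 - truth**2) / n
    return length_weight * length + region_weight * region, grad


def loss(pred: np.ndarray, truth: np.ndarray, kind: str = "dice",
         **kwargs) -> tuple[float, np.ndarray]:
    """Dispatch by loss kind: 'ce', 'dice' or 'active_contour'."""
    fns = {"ce": ce_loss, "dice": dice_loss, "active_contour": active_contour_loss}
    if kind not in fns:
        raise ParameterError(f"unknown loss kind {kind!r}")
    return fns[kind](pred, truth, **kwargs)
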