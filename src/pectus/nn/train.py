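"""Adam training loop with early stopping on validation loss.

Deterministic for a fixed seed: the train/validation split, batch order and
weight initialization all derive from integer seeds, and all arithmetic is
plain numpy.  Training runs until the validation loss has not improved for
``patience`` epochs (or ``max_epochs``), then the best-validation weights
are restored.
"""

from __future__ import annotations

import numpy as np

from ..errors import ParameterError, PectusError
from .losses import loss as loss_fn
from .unet import TrainConfig, UNet

__all__ = ["train", "TrainingDiverged", "dice_score"]


class TrainingDiverged(PectusError):
    """The loss became non-finite during optimization."""


def dice_score(pred_mask: np.ndarray, truth_mask: np.ndarray) -> float:
    """Hard Dice overlap between two binary masks (both-empty = 1)."""
    a = np.asarray(pred_mask, bool)
    b = np.asarray(truth_mask, bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * float(np.logical_and(a, b).sum()) / float(denom)


def _stack_pairs(pairs) -> tuple[np.ndarray, np.ndarray]:
    imgs = np.stack([np.asarray(im, dtype=np.float32) for im, _ in pairs])[:, None]
    masks = np.stack([np.asarray(m, dtype=np.float32) for _, m in pairs])[:, None]
    return imgs, masks


def train(model: UNet, pairs, cfg: TrainConfig | None = None, val_pairs=None):
    """Optimize ``model`` on (image, mask) pairs; returns (model, history).

    ``pairs`` holds float images (intensities roughly in [0, 1]) and binary
    masks of identical shape.  Without an explicit ``val_pairs`` the last
    ``val_fraction`` of a seeded shuffle is held out; the split is disjoint
    by construction.  ``history`` is one dict per epoch with train/val loss
    and the mean validation Dice of the thresholded predictions.
    """
    cfg = cfg or model.cfg
    cfg.validate()
    if len(pairs) + (len(val_pairs) if val_pairs else 0) < 2:
        raise ParameterError("need at least 2 (image, mask) pairs")
    rng = np.random.default_rng(cfg.seed)
    if val_pairs is None:
        order = rng.permutation(len(pairs))
        n_val = max(1, int(round(cfg.val_fraction * len(pairs))))
        if n_val >= len(pairs):
            raise ParameterError("val_fraction leaves no training data")
        val_idx, train_idx = order[:n_val], order[n_val:]
        val_pairs = [pairs[i] for i in val_idx]
        pairs = [pairs[i] for i in train_idx]
    x_tr, y_tr = _stack_pairs(pairs)
    x_va, y_va = _stack_pairs(val_pairs)

    kwargs = {}
    if cfg.loss_kind == "active_contour":
        kwargs = {"length_weight": cfg.ac_length_weight,
                  "region_weight": cfg.ac_region_weight}

    m_state = {k: np.zeros_like(v) for k, v in model.params.items()}
    v_state = {k: np.zeros_like(v) for k, v in model.params.items()}
    b1, b2, eps = 0.9, 0.999, 1e-8
    step = 0
    history: list[dict] = []
    best = (np.inf, None, -1)  # (val loss, weights, epoch)

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(x_tr))
        train_losses = []
        for start in range(0, len(order), cfg.batch_size):
            sel = order[start:start + cfg.batch_size]
            prob = model.forward(x_tr[sel], keep_cache=True)
            value, dprob = loss_fn(prob, y_tr[sel], cfg.loss_kind, **kwargs)
            if not np.isfinite(value):
                raise TrainingDiverged(
                    f"non-finite {cfg.loss_kind} loss at epoch {epoch}, "
                    f"step {step}"
                )
            train_losses.append(value)
            grads = model.backward(dprob)
            step += 1
            lr_t = cfg.learning_rate * np.sqrt(1 - b2**step) / (1 - b1**step)
            for k, g in grads.items():
                g = g.astype(np.float32)
                m_state[k] = b1 * m_state[k] + (1 - b1) * g
                v_state[k] = b2 * v_state[k] + (1 - b2) * g * g
                model.params[k] -= lr_t * m_state[k] / (np.sqrt(v_state[k]) + eps)

        val_losses, val_dices = [], []
        for start in range(0, len(x_va), cfg.batch_size):
            sl = slice(start, start + cfg.batch_size)
            prob = model.forward(x_va[sl])
            value, _ = loss_fn(prob, y_va[sl], cfg.loss_kind, **kwargs)
            val_losses.append(value * (sl.indices(len(x_va))[1] - sl.indices(len(x_va))[0]))
            for p, t in zip(prob[:, 0], y_va[sl][:, 0]):
                val_dices.append(dice_score(p > 0.5, t > 0.5))
        val_loss = float(np.sum(val_losses) / len(x_va))
        history.append({
            "epoch": epoch,
            "train_loss": float(np.mean(train_losses)),
            "val_loss": val_loss,
            "val_dice": float(np.mean(val_dices)),
        })
        if val_loss < best[0]:
            best = (val_loss, {k: v.copy() for k, v in model.params.items()}, epoch)
        elif epoch - best[2] >= cfg.patience:
            break

    if best[1] is not None:
        model.params = best[1]
    return model, history
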