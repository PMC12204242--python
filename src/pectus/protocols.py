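"""Canned evaluation protocols built from the library pieces.

``segmentation_benchmark`` is the package's reference segmentation
evaluation: train the compact U-Net on seeded synthetic phantom slices and
report mean Dice / IoU of the post-processed predictions on a held-out set.
The problem sizes (250 phantoms split 200/50, 128-pixel grids, 8 base
filters) keep the run tractable on a single CPU while leaving the task
representative: three intensity bands with noise, variable anatomy, and the
full post-processing path.
"""

from __future__ import annotations

import numpy as np

from .agreement import dice, iou
from .nn import TrainConfig, UNet, train
from .phantom import AxialSlice, make_phantom_slice, random_params
from .seg import normalize_intensity, predict_mask

__all__ = ["make_training_set", "segmentation_benchmark"]


def make_training_set(n: int, image_size: int = 128, seed: int = 0,
                      noise_sd: float = 6.0):
    """n seeded random phantom (image, mask) pairs, network-normalized."""
    rng = np.random.default_rng(seed)
    pairs = []
    for _ in range(n):
        p = random_params(rng, image_size=image_size, noise_sd=noise_sd)
        sl, mask = make_phantom_slice(p)
        pairs.append((normalize_intensity(sl.image), mask.astype(np.float32)))
    return pairs


def segmentation_benchmark(seed: int = 0, n_train: int = 200, n_val: int = 50,
                           image_size: int = 128, base_filters: int = 8,
                           depth: int = 4, loss_kind: str = "dice",
                           learning_rate: float = 1e-4, max_epochs: int = 20,
                           patience: int = 5) -> dict:
    """Train on phantoms and score held-out slices; returns the summary.

    The held-out slices are never seen during optimization or early
    stopping; predictions go through the full thresholding and largest-
    component post-processing before scoring.
    """
    pairs = make_training_set(n_train + n_val, image_size=image_size, seed=seed)
    train_pairs, val_pairs = pairs[:n_train], pairs[n_train:]
    cfg = TrainConfig(input_size=image_size, base_filters=base_filters,
                      depth=depth, loss_kind=loss_kind,
                      learning_rate=learning_rate, max_epochs=max_epochs,
                      patience=patience, seed=seed)
    model = UNet(cfg)
    model, history = train(model, train_pairs, cfg, val_pairs=val_pairs)
    dices, ious = [], []
    for img, truth in val_pairs:
        sl = AxialSlice(image=img, spacing_mm=1.0)
        pred = predict_mask(model, sl, normalized=True)
        if pred is None:
            pred = np.zeros_like(truth, dtype=bool)
        dices.append(dice(pred, truth > 0.5))
        ious.append(iou(pred, truth > 0.5))
    return {
        "mean_dice": float(np.mean(dices)),
        "mean_iou": float(np.mean(ious)),
        "n_train": n_train,
        "n_val": n_val,
        "epochs_run": len(history),
        "history": history,
        "model": model,
    }
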