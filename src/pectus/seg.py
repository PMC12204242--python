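"""Segmentation-stage pre/post-processing: resampling, augmentation, masks.

Augmentation families — rotations, isotropic rescalings, flips — are applied
independently (never composed), each producing one output pair per family
member; with the default configuration one input expands to 20 pairs
(11 rotations + 7 scales + 2 flips).  Geometric transforms use bilinear
interpolation with reflect padding for intensities and nearest-neighbor for
masks, so out-of-frame pixels never invent new anatomy and masks stay
binary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure, transform

from .errors import ParameterError
from .phantom import AxialSlice, INTENSITY_BACKGROUND, INTENSITY_BODY

__all__ = ["AugmentConfig", "augment", "resample", "resample_mask",
           "normalize_intensity", "predict_mask", "postprocess_probability"]


@dataclass(frozen=True)
class AugmentConfig:
    """Independent augmentation families and their members."""

    rotation_degrees: tuple = tuple(range(-25, 30, 5))          # 11 values
    scale_factors: tuple = tuple(round(0.85 + 0.05 * i, 2) for i in range(7))
    flips: tuple = ("horizontal", "vertical")

    @property
    def expansion_factor(self) -> int:
        return len(self.rotation_degrees) + len(self.scale_factors) + len(self.flips)

    def validate(self) -> None:
        if self.expansion_factor == 0:
            raise ParameterError("empty augmentation config")
        for f in self.flips:
            if f not in ("horizontal", "vertical"):
                raise ParameterError(f"unknown flip {f!r}")
        for s in self.scale_factors:
            if s <= 0:
                raise ParameterError(f"scale factor must be > 0, got {s}")


def _rotate(image: np.ndarray, angle: float, order: int) -> np.ndarray:
    return ndimage.rotate(image, angle, reshape=False, order=order,
                          mode="reflect", prefilter=False)


def _scale(image: np.ndarray, factor: float, order: int) -> np.ndarray:
    """Isotropic zoom about the image center, reflect-padded/cropped back."""
    h, w = image.shape
    zoomed = ndimage.zoom(image, factor, order=order, mode="reflect",
                          prefilter=False, grid_mode=True)
    zh, zw = zoomed.shape
    if zh >= h:
        r0, c0 = (zh - h) // 2, (zw - w) // 2
        return zoomed[r0:r0 + h, c0:c0 + w]
    pr, pc = h - zh, w - zw
    pad = ((pr // 2, pr - pr // 2), (pc // 2, pc - pc // 2))
    return np.pad(zoomed, pad, mode="reflect")


def augment(image: np.ndarray, mask: np.ndarray,
            cfg: AugmentConfig | None = None) -> list[tuple[np.ndarray, np.ndarray]]:
    """Expand one (image, mask) pair into one pair per family member."""
    cfg = cfg or AugmentConfig()
    cfg.validate()
    image = np.asarray(image, dtype=np.float32)
    mask = np.asarray(mask)
    if image.shape != mask.shape:
        raise ParameterError(
            f"image {image.shape} and mask {mask.shape} are not congruent"
        )
    out: list[tuple[np.ndarray, np.ndarray]] = []
    mask_f = mask.astype(np.float32)
    for angle in cfg.rotation_degrees:
        if angle == 0:
            out.append((image.copy(), mask.copy()))
        else:
            out.append((_rotate(image, angle, 1),
                        _rotate(mask_f, angle, 0).astype(mask.dtype)))
    for s in cfg.scale_factors:
        if s == 1.0:
            out.append((image.copy(), mask.copy()))
        else:
            out.append((_scale(image, s, 1),
                        _scale(mask_f, s, 0).astype(mask.dtype)))
    for f in cfg.flips:
        axis = 1 if f == "horizontal" else 0
        out.append((np.flip(image, axis).copy(), np.flip(mask, axis).copy()))
    return out


def resample(slice_: AxialSlice, size: int) -> AxialSlice:
    """Bilinear resample to ``size`` x ``size``, preserving physical extent."""
    if size < 32:
        raise ParameterError(f"target size must be >= 32, got {size}")
    img = np.asarray(slice_.image)
    h, w = img.shape
    if (h, w) == (size, size):
        return AxialSlice(image=img.copy(), spacing_mm=slice_.spacing_mm,
                          z_index=slice_.z_index)
    out = transform.resize(img.astype(float), (size, size), order=1,
                           mode="reflect", anti_aliasing=size < h,
                           preserve_range=True).astype(np.float32)
    new_spacing = slice_.spacing_mm * h / size
    return AxialSlice(image=out, spacing_mm=new_spacing, z_index=slice_.z_index)


def resample_mask(mask: np.ndarray, size: int) -> np.ndarray:
    """Nearest-neighbor mask resample to ``size`` x ``size``."""
    mask = np.asarray(mask)
    if mask.shape == (size, size):
        return mask.copy()
    out = transform.resize(mask.astype(float), (size, size), order=0,
                           mode="constant", anti_aliasing=False,
                           preserve_range=True)
    return out > 0.5


def normalize_intensity(image: np.ndarray) -> np.ndarray:
    """Map phantom/CT-style intensities to roughly [0, 1] for the network."""
    lo, hi = INTENSITY_BACKGROUND, INTENSITY_BODY
    return ((np.asarray(image, dtype=np.float32) - lo) / (hi - lo)).clip(-0.5, 1.5)


def postprocess_probability(prob: np.ndarray, threshold: float = 0.5) -> np.ndarray | None:
    """Threshold, keep the largest connected component, fill holes.

    Returns None (a no-segmentation signal) when nothing survives the
    threshold.
    """
    if not 0 < threshold < 1:
        raise ParameterError(f"threshold must be in (0, 1), got {threshold}")
    raw = np.asarray(prob) > threshold
    if not raw.any():
        return None
    labels, n = measure.label(raw, connectivity=2, return_num=True)
    if n > 1:
        largest = 1 + int(np.argmax(np.bincount(labels.ravel())[1:]))
        raw = labels == largest
    return ndimage.binary_fill_holes(raw)


def predict_mask(model, slice_: AxialSlice, threshold: float = 0.5,
                 normalized: bool = False) -> np.ndarray | None:
    """Segment one slice with a trained model.

    The slice must already match the model input size.  The probability map
    is thresholded and post-processed so any returned mask is a single
    filled component; None signals an empty segmentation.
    """
    img = np.asarray(slice_.image, dtype=np.float32)
    if img.shape[0] != model.cfg.input_size or img.shape[1] != model.cfg.input_size:
        raise ParameterError(
            f"slice is {img.shape}, model expects "
            f"{model.cfg.input_size}x{model.cfg.input_size}; resample first"
        )
    x = img if normalized else normalize_intensity(img)
    prob = model.forward(x[None, None])[0, 0]
    return postprocess_probability(prob, threshold)
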