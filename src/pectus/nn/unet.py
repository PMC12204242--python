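"""The U-shaped encoder-decoder segmentation network.

Classic configuration: each encoder level applies two 3x3 convolutions with
ReLU and then a 2x2 max-pool; the bottleneck applies two more convolutions;
each decoder level applies a 2x2 up-convolution, concatenates the matching
encoder feature map through a skip connection, and applies two 3x3
convolutions with ReLU; a final 1x1 convolution with a sigmoid yields a
per-pixel foreground probability.  Filter counts double per level from
``base_filters``.  At the default depth of 4 the network has the classic 23
weighted layers (18 3x3 convolutions, 4 up-convolutions, 1 1x1 convolution).
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from ..errors import ParameterError
from . import ops

__all__ = ["TrainConfig", "UNet"]


@dataclass
class TrainConfig:
    """Architecture and optimization settings for the segmentation model."""

    input_size: int = 256
    base_filters: int = 16
    depth: int = 4
    loss_kind: str = "dice"          # ce | dice | active_contour
    learning_rate: float = 1e-4      # Adam step size
    max_epochs: int = 60
    patience: int = 10               # early-stopping patience, epochs
    batch_size: int = 4
    val_fraction: float = 0.2
    seed: int = 0
    ac_length_weight: float = 1.0    # active-contour loss term weights
    ac_region_weight: float = 1.0

    def validate(self) -> None:
        if self.learning_rate <= 0:
            raise ParameterError("learning_rate must be > 0")
        if self.input_size % (2 ** self.depth) != 0:
            raise ParameterError(
                f"input_size {self.input_size} is not divisible by "
                f"2**depth = {2 ** self.depth}"
            )
        if self.loss_kind not in ("ce", "dice", "active_contour"):
            raise ParameterError(f"unknown loss_kind {self.loss_kind!r}")
        if self.base_filters < 1 or self.depth < 1:
            raise ParameterError("base_filters and depth must be >= 1")


class UNet:
    """Pure-numpy U-Net for binary segmentation of axial slices."""

    def __init__(self, cfg: TrainConfig):
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.params: dict[str, np.ndarray] = {}
        bf, depth = cfg.base_filters, cfg.depth

        def conv(name, c_in, c_out):
            std = np.sqrt(2.0 / (c_in * 9))
            self.params[f"{name}_w"] = rng.normal(0, std, (c_out, c_in, 3, 3)).astype(np.float32)
            self.params[f"{name}_b"] = np.zeros(c_out, dtype=np.float32)

        def upconv(name, c_in, c_out):
            std = np.sqrt(2.0 / (c_in * 4))
            self.params[f"{name}_w"] = rng.normal(0, std, (c_in, c_out, 2, 2)).astype(np.float32)
            self.params[f"{name}_b"] = np.zeros(c_out, dtype=np.float32)

        c_in = 1
        for lv in range(depth):
            f = bf * 2 ** lv
            conv(f"enc{lv}a", c_in, f)
            conv(f"enc{lv}b", f, f)
            c_in = f
        fb = bf * 2 ** depth
        conv("bota", c_in, fb)
        conv("botb", fb, fb)
        c_in = fb
        for lv in reversed(range(depth)):
            f = bf * 2 ** lv
            upconv(f"up{lv}", c_in, f)
            conv(f"dec{lv}a", 2 * f, f)
            conv(f"dec{lv}b", f, f)
            c_in = f
        # Final 1x1 convolution, stored as a (1, C, 1, 1) kernel.
        std = np.sqrt(2.0 / c_in)
        self.params["out_w"] = rng.normal(0, std, (1, c_in, 1, 1)).astype(np.float32)
        self.params["out_b"] = np.zeros(1, dtype=np.float32)

    # -- introspection ----------------------------------------------------

    def n_weighted_layers(self) -> int:
        """Convolutional + up-convolutional layer count (23 at depth 4)."""
        d = self.cfg.depth
        return 2 * d + 2 + 3 * d + 1

    def checksum(self) -> int:
        """CRC32 over all parameter bytes, for reproducibility checks."""
        crc = 0
        for name in sorted(self.params):
            crc = zlib.crc32(self.params[name].tobytes(), crc)
        return crc

    # -- forward / backward ------------------------------------------------

    def forward(self, x: np.ndarray, keep_cache: bool = False) -> np.ndarray:
        """Probability map for a batch.  x: (N, 1, H, W) in [0, 1]."""
        if x.ndim != 4 or x.shape[1] != 1:
            raise ParameterError(f"expected (N, 1, H, W) input, got {x.shape}")
        if x.shape[2] % (2 ** self.cfg.depth) or x.shape[3] % (2 ** self.cfg.depth):
            raise ParameterError(
                f"input {x.shape[2]}x{x.shape[3]} not divisible by 2**depth"
            )
        p = self.params
        cache: dict = {}
        h = x.astype(np.float32)
        skips = []
        for lv in range(self.cfg.depth):
            h, cache[f"enc{lv}a"] = ops.conv3_forward(h, p[f"enc{lv}a_w"], p[f"enc{lv}a_b"])
            h, cache[f"enc{lv}a_r"] = ops.relu_forward(h)
            h, cache[f"enc{lv}b"] = ops.conv3_forward(h, p[f"enc{lv}b_w"], p[f"enc{lv}b_b"])
            h, cache[f"enc{lv}b_r"] = ops.relu_forward(h)
            skips.append(h)
            h, cache[f"pool{lv}"] = ops.maxpool2_forward(h)
        h, cache["bota"] = ops.conv3_forward(h, p["bota_w"], p["bota_b"])
        h, cache["bota_r"] = ops.relu_forward(h)
        h, cache["botb"] = ops.conv3_forward(h, p["botb_w"], p["botb_b"])
        h, cache["botb_r"] = ops.relu_forward(h)
        for lv in reversed(range(self.cfg.depth)):
            h, cache[f"up{lv}"] = ops.upconv2_forward(h, p[f"up{lv}_w"], p[f"up{lv}_b"])
            h = np.concatenate([skips[lv], h], axis=1)
            h, cache[f"dec{lv}a"] = ops.conv3_forward(h, p[f"dec{lv}a_w"], p[f"dec{lv}a_b"])
            h, cache[f"dec{lv}a_r"] = ops.relu_forward(h)
            h, cache[f"dec{lv}b"] = ops.conv3_forward(h, p[f"dec{lv}b_w"], p[f"dec{lv}b_b"])
            h, cache[f"dec{lv}b_r"] = ops.relu_forward(h)
        z = np.einsum("nchw,oc->nohw", h, p["out_w"][:, :, 0, 0]) + p["out_b"][None, :, None, None]
        prob = ops.sigmoid(z)
        if keep_cache:
            cache["out_h"] = h
            cache["prob"] = prob
            self._cache = cache
        return prob

    def backward(self, dprob: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of a scalar loss given d(loss)/d(probability map)."""
        cache = self._cache
        p = self.params
        grads: dict[str, np.ndarray] = {}
        prob = cache["prob"]
        dz = (dprob * prob * (1.0 - prob)).astype(np.float32)
        h = cache["out_h"]
        grads["out_w"] = np.einsum("nohw,nchw->oc", dz, h, optimize=True)[:, :, None, None]
        grads["out_b"] = dz.sum(axis=(0, 2, 3))
        dh = np.einsum("nohw,oc->nchw", dz, p["out_w"][:, :, 0, 0])
        for lv in range(self.cfg.depth):
            dh = ops.relu_backward(dh, cache[f"dec{lv}b_r"])
            dh, grads[f"dec{lv}b_w"], grads[f"dec{lv}b_b"] = ops.conv3_backward(dh, cache[f"dec{lv}b"])
            dh = ops.relu_backward(dh, cache[f"dec{lv}a_r"])
            dh, grads[f"dec{lv}a_w"], grads[f"dec{lv}a_b"] = ops.conv3_backward(dh, cache[f"dec{lv}a"])
            f = self.cfg.base_filters * 2 ** lv
            dskip, dup = dh[:, :f], dh[:, f:]
            dh, grads[f"up{lv}_w"], grads[f"up{lv}_b"] = ops.upconv2_backward(dup, cache[f"up{lv}"])
            cache[f"dskip{lv}"] = dskip
        dh = ops.relu_backward(dh, cache["botb_r"])
        dh, grads["botb_w"], grads["botb_b"] = ops.conv3_backward(dh, cache["botb"])
        dh = ops.relu_backward(dh, cache["bota_r"])
        dh, grads["bota_w"], grads["bota_b"] = ops.conv3_backward(dh, cache["bota"])
        for lv in reversed(range(self.cfg.depth)):
            dh = ops.maxpool2_backward(dh, cache[f"pool{lv}"])
            dh = dh + cache[f"dskip{lv}"]
            dh = ops.relu_backward(dh, cache[f"enc{lv}b_r"])
            dh, grads[f"enc{lv}b_w"], grads[f"enc{lv}b_b"] = ops.conv3_backward(dh, cache[f"enc{lv}b"])
            dh = ops.relu_backward(dh, cache[f"enc{lv}a_r"])
            dh, grads[f"enc{lv}a_w"], grads[f"enc{lv}a_b"] = ops.conv3_backward(dh, cache[f"enc{lv}a"])
        self._cache = None
        return grads

    # -- serialization -----------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Weights as .npz next to a JSON manifest of the configuration."""
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.params)
        manifest = {"config": asdict(self.cfg), "checksum": self.checksum(),
                    "n_weighted_layers": self.n_weighted_layers()}
        path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "UNet":
        path = Path(path)
        manifest = json.loads(path.with_suffix(".json").read_text())
        model = cls(TrainConfig(**manifest["config"]))
        with np.load(path.with_suffix(".npz")) as data:
            for name in model.params:
                model.params[name] = data[name]
        return model
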