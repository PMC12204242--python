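"""Forward/backward primitives: conv3x3, maxpool2, upconv2, relu, sigmoid.

Tensors are (N, C, H, W) float32.  Each forward returns (output, cache); each
backward takes (grad_out, cache) and returns the input gradient plus any
parameter gradients.  Convolution input gradients are themselves computed as
convolutions with the spatially flipped, channel-transposed kernel, so every
heavy operation is a single BLAS matmul.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

F32 = np.float32


def _im2col3(x: np.ndarray) -> np.ndarray:
    """(N, C, H, W) -> (N*H*W, C*9) patches of the zero-padded input."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = sliding_window_view(xp, (3, 3), axis=(2, 3))  # (N, C, H, W, 3, 3)
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n * h * w, c * 9
    )


def conv3_forward(x: np.ndarray, weight: np.ndarray, bias: np.ndarray):
    """Same-padded 3x3 convolution.  weight: (F, C, 3, 3), bias: (F,)."""
    n, c, h, w = x.shape
    f = weight.shape[0]
    cols = _im2col3(x)
    out = cols @ weight.reshape(f, c * 9).T
    out += bias
    out = out.reshape(n, h, w, f).transpose(0, 3, 1, 2)
    return np.ascontiguousarray(out), (cols, x.shape, weight)


def conv3_backward(dout: np.ndarray, cache):
    cols, x_shape, weight = cache
    n, c, h, w = x_shape
    f = weight.shape[0]
    dcols = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)).reshape(n * h * w, f)
    dweight = (dcols.T @ cols).reshape(f, c, 3, 3)
    dbias = dcols.sum(axis=0)
    # Input gradient = conv of dout with the flipped, transposed kernel.
    w_t = np.ascontiguousarray(weight[:, :, ::-1, ::-1].transpose(1, 0, 2, 3))
    dx, _ = conv3_forward(dout, w_t, np.zeros(c, dtype=dout.dtype))
    return dx, dweight, dbias


def relu_forward(x: np.ndarray):
    out = np.maximum(x, 0)
    return out, (x > 0)


def relu_backward(dout: np.ndarray, mask: np.ndarray):
    return dout * mask


def maxpool2_forward(x: np.ndarray):
    n, c, h, w = x.shape
    xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    xr = np.ascontiguousarray(xr).reshape(n, c, h // 2, w // 2, 4)
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    return out, (idx, x.shape)


def maxpool2_backward(dout: np.ndarray, cache):
    idx, x_shape = cache
    n, c, h, w = x_shape
    dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=dout.dtype)
    np.put_along_axis(dxr, idx[..., None], dout[..., None], axis=-1)
    dx = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
    return np.ascontiguousarray(dx).reshape(n, c, h, w)


def upconv2_forward(x: np.ndarray, weight: np.ndarray, bias: np.ndarray):
    """2x2 stride-2 transposed convolution.  weight: (C, F, 2, 2)."""
    n, c, h, w = x.shape
    f = weight.shape[1]
    out6 = np.einsum("ncij,cfab->nfiajb", x, weight, optimize=True)
    out = out6.reshape(n, f, 2 * h, 2 * w) + bias[None, :, None, None]
    return np.ascontiguousarray(out), (x, weight)


def upconv2_backward(dout: np.ndarray, cache):
    x, weight = cache
    n, c, h, w = x.shape
    f = weight.shape[1]
    d6 = dout.reshape(n, f, h, 2, w, 2)
    dx = np.einsum("nfiajb,cfab->ncij", d6, weight, optimize=True)
    dweight = np.einsum("ncij,nfiajb->cfab", x, d6, optimize=True)
    dbias = dout.sum(axis=(0, 2, 3))
    return dx, dweight, dbias


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out
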