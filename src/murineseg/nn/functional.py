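"""Low-level differentiable operations for the 2D U-Net.

Everything is plain numpy: convolutions are im2col matrix products, and each
``*_forward`` returns the minimal cache its ``*_backward`` needs.  Tensors
are ``(batch, channels, height, width)``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "conv3_forward", "conv3_backward", "conv3_input_grad",
    "conv1_forward", "conv1_backward",
    "relu_forward", "relu_backward",
    "maxpool2_forward", "maxpool2_backward",
    "upconv2_forward", "upconv2_backward",
    "sigmoid", "bce_loss_and_grad",
]


def _im2col3(x: np.ndarray) -> np.ndarray:
    """(b, c, h, w) -> (b*h*w, c*9) patches of the zero-padded input."""
    b, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = sliding_window_view(xp, (3, 3), axis=(2, 3))  # (b, c, h, w, 3, 3)
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(b * h * w, c * 9)


def conv3_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """3x3 'same' convolution.  W: (c_out, c_in, 3, 3), b: (c_out,)."""
    bs, c, h, w = x.shape
    o = W.shape[0]
    cols = _im2col3(x)
    y = cols @ W.reshape(o, c * 9).T + b
    y = y.reshape(bs, h, w, o).transpose(0, 3, 1, 2)
    return y, (cols, x.shape)


def conv3_input_grad(dy: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Gradient w.r.t. the input: correlation of dy with the flipped kernel."""
    Wflip = np.ascontiguousarray(W.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1])
    dx, _ = conv3_forward(dy, Wflip, np.zeros(Wflip.shape[0], dtype=dy.dtype))
    return dx


def conv3_backward(dy: np.ndarray, cache, W: np.ndarray):
    cols, xshape = cache
    bs, c, h, w = xshape
    o = W.shape[0]
    dyf = dy.transpose(0, 2, 3, 1).reshape(bs * h * w, o)
    dW = (dyf.T @ cols).reshape(W.shape)
    db = dyf.sum(axis=0)
    dx = conv3_input_grad(dy, W)
    return dx, dW, db


def conv1_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """1x1 convolution (channel mixing).  W: (c_out, c_in)."""
    y = np.einsum("bchw,oc->bohw", x, W, optimize=True) + b[None, :, None, None]
    return y, x


def conv1_backward(dy: np.ndarray, cache, W: np.ndarray):
    x = cache
    dW = np.einsum("bohw,bchw->oc", dy, x, optimize=True)
    db = dy.sum(axis=(0, 2, 3))
    dx = np.einsum("bohw,oc->bchw", dy, W, optimize=True)
    return dx, dW, db


def relu_forward(x: np.ndarray):
    mask = x > 0
    return x * mask, mask


def relu_backward(dy: np.ndarray, mask: np.ndarray) -> np.ndarray:
    return dy * mask


def maxpool2_forward(x: np.ndarray):
    """2x2 max pooling with stride 2; ties resolve to the first maximum."""
    b, c, h, w = x.shape
    xr = x.reshape(b, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(b, c, h // 2, w // 2, 4)
    idx = xr.argmax(axis=-1)
    y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    return y, (idx, x.shape)


def maxpool2_backward(dy: np.ndarray, cache) -> np.ndarray:
    idx, xshape = cache
    b, c, h, w = xshape
    dflat = np.zeros((b, c, h // 2, w // 2, 4), dtype=dy.dtype)
    np.put_along_axis(dflat, idx[..., None], dy[..., None], axis=-1)
    return dflat.reshape(b, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(b, c, h, w)


def upconv2_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """2x2 stride-2 transposed convolution (learned unpooling).

    W: (c_in, c_out, 2, 2); output is (b, c_out, 2h, 2w) — each input pixel
    paints one non-overlapping 2x2 output block.
    """
    bs, c, h, w = x.shape
    o = W.shape[1]
    y = np.einsum("bchw,cokl->bohkwl", x, W, optimize=True).reshape(bs, o, 2 * h, 2 * w)
    return y + b[None, :, None, None], x


def upconv2_backward(dy: np.ndarray, cache, W: np.ndarray):
    x = cache
    bs, o = dy.shape[0], dy.shape[1]
    h, w = dy.shape[2] // 2, dy.shape[3] // 2
    dyr = dy.reshape(bs, o, h, 2, w, 2).transpose(0, 1, 2, 4, 3, 5)  # (b, o, h, w, 2, 2)
    dx = np.einsum("bohwkl,cokl->bchw", dyr, W, optimize=True)
    dW = np.einsum("bchw,bohwkl->cokl", x, dyr, optimize=True)
    db = dy.sum(axis=(0, 2, 3))
    return dx, dW, db


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_loss_and_grad(logits: np.ndarray, targets: np.ndarray):
    """Mean binary cross-entropy from logits, with its gradient w.r.t. logits.

    Uses the numerically stable log-sum-exp form; the gradient is the familiar
    ``(sigmoid(z) - y) / n``.
    """
    z = logits
    y = targets
    loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    p = sigmoid(z)
    n = z.size
    return float(loss.mean()), ((p - y) / n).astype(z.dtype)
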