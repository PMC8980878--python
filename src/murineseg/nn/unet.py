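"""The 2D U-Net: encoder, bottleneck, decoder with skip concatenation.

Each level applies two 3x3 convolutions with rectified-linear activations;
the encoder downsamples with 2x2 max pooling while doubling the channel
count, the decoder upsamples with 2x2 transposed convolutions and
concatenates the matching encoder feature map, and a 1x1 sigmoid head emits
a per-pixel lung probability.  Parameters live in a flat ``{name: array}``
dict; every name starting with ``enc`` or ``bottleneck`` belongs to the
encoder (the part frozen during transfer learning), everything else to the
decoder.
"""

from __future__ import annotations

import numpy as np

from ..errors import ArchitectureError
from . import functional as F

__all__ = ["UNet", "is_encoder_param"]


def is_encoder_param(name: str) -> bool:
    """Encoder/decoder split used for transfer learning: all blocks up to and
    including the bottleneck count as encoder."""
    return name.startswith("enc") or name.startswith("bottleneck")


def _he(rng: np.random.Generator, shape, fan_in: int, dtype) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(dtype)


class UNet:
    """2D U-Net with ``depth`` pooling levels and ``base_filters`` channels at
    the first level, doubling per level.  Input height and width must be
    divisible by ``2**depth``; the output has the input's spatial size."""

    def __init__(self, depth: int = 4, base_filters: int = 32, dtype=np.float32):
        if depth < 1:
            raise ArchitectureError("depth must be >= 1")
        self.depth = depth
        self.base_filters = base_filters
        self.dtype = dtype

    # -- parameters ---------------------------------------------------------

    def init_params(self, seed: int = 0) -> dict[str, np.ndarray]:
        rng = np.random.default_rng(seed)
        p: dict[str, np.ndarray] = {}
        dt = self.dtype

        def conv(name, cin, cout):
            p[f"{name}.W"] = _he(rng, (cout, cin, 3, 3), cin * 9, dt)
            p[f"{name}.b"] = np.zeros(cout, dtype=dt)

        cin = 1
        for i in range(self.depth):
            f = self.base_filters * 2**i
            conv(f"enc{i}.conv1", cin, f)
            conv(f"enc{i}.conv2", f, f)
            cin = f
        fb = self.base_filters * 2**self.depth
        conv("bottleneck.conv1", cin, fb)
        conv("bottleneck.conv2", fb, fb)
        cin = fb
        for i in reversed(range(self.depth)):
            f = self.base_filters * 2**i
            p[f"dec{i}.up.W"] = _he(rng, (cin, f, 2, 2), cin * 4, dt)
            p[f"dec{i}.up.b"] = np.zeros(f, dtype=dt)
            conv(f"dec{i}.conv1", 2 * f, f)
            conv(f"dec{i}.conv2", f, f)
            cin = f
        p["head.W"] = _he(rng, (1, cin), cin, dt)
        p["head.b"] = np.zeros(1, dtype=dt)
        return p

    def check_params(self, params: dict[str, np.ndarray]) -> None:
        ref = self.init_params(0)
        if set(ref) != set(params):
            missing = set(ref) ^ set(params)
            raise ArchitectureError(f"weight set does not match architecture: {sorted(missing)}")
        for k in ref:
            if ref[k].shape != params[k].shape:
                raise ArchitectureError(
                    f"shape mismatch for {k}: expected {ref[k].shape}, got {params[k].shape}"
                )

    # -- forward / backward -------------------------------------------------

    def _check_input(self, x: np.ndarray) -> None:
        if x.ndim != 4 or x.shape[1] != 1:
            raise ArchitectureError(f"expected input (batch, 1, H, W), got {x.shape}")
        m = 2**self.depth
        if x.shape[2] % m or x.shape[3] % m:
            raise ArchitectureError(
                f"input H, W must be divisible by 2**depth={m}, got {x.shape[2:]}"
            )

    def forward(self, params: dict, x: np.ndarray, want_cache: bool = True):
        """Return per-pixel logits ``(b, 1, H, W)`` and (optionally) the cache
        for :meth:`backward`."""
        self._check_input(x)
        x = x.astype(self.dtype, copy=False)
        cache: dict = {}
        skips = []
        h = x
        for i in range(self.depth):
            h, cache[f"enc{i}"] = self._block(params, f"enc{i}", h, want_cache)
            skips.append(h)
            h, cache[f"pool{i}"] = F.maxpool2_forward(h)
        h, cache["bottleneck"] = self._block(params, "bottleneck", h, want_cache)
        for i in reversed(range(self.depth)):
            h, cache[f"up{i}"] = F.upconv2_forward(h, params[f"dec{i}.up.W"], params[f"dec{i}.up.b"])
            cache[f"cat{i}"] = skips[i].shape[1]
            h = np.concatenate([skips[i], h], axis=1)
            h, cache[f"dec{i}"] = self._block(params, f"dec{i}", h, want_cache)
        logits, cache["head"] = F.conv1_forward(h, params["head.W"], params["head.b"])
        if not want_cache:
            return logits, None
        return logits, cache

    def _block(self, params, name, h, want_cache):
        h, c1 = F.conv3_forward(h, params[f"{name}.conv1.W"], params[f"{name}.conv1.b"])
        h, r1 = F.relu_forward(h)
        h, c2 = F.conv3_forward(h, params[f"{name}.conv2.W"], params[f"{name}.conv2.b"])
        h, r2 = F.relu_forward(h)
        return h, ((c1, r1, c2, r2) if want_cache else None)

    def backward(self, params: dict, cache: dict, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of the scalar loss w.r.t. every parameter, given the
        gradient w.r.t. the logits."""
        grads: dict[str, np.ndarray] = {}
        dh, grads["head.W"], grads["head.b"] = F.conv1_backward(dlogits, cache["head"], params["head.W"])
        for i in range(self.depth):
            dh = self._block_backward(params, grads, f"dec{i}", cache[f"dec{i}"], dh)
            nskip = cache[f"cat{i}"]
            dskip, dup = dh[:, :nskip], dh[:, nskip:]
            dh, grads[f"dec{i}.up.W"], grads[f"dec{i}.up.b"] = F.upconv2_backward(
                dup, cache[f"up{i}"], params[f"dec{i}.up.W"]
            )
            cache[f"dskip{i}"] = dskip
        dh = self._block_backward(params, grads, "bottleneck", cache["bottleneck"], dh)
        for i in reversed(range(self.depth)):
            dh = F.maxpool2_backward(dh, cache[f"pool{i}"])
            dh = dh + cache[f"dskip{i}"]
            dh = self._block_backward(params, grads, f"enc{i}", cache[f"enc{i}"], dh)
        return grads

    def _block_backward(self, params, grads, name, bcache, dh):
        c1, r1, c2, r2 = bcache
        dh = F.relu_backward(dh, r2)
        dh, grads[f"{name}.conv2.W"], grads[f"{name}.conv2.b"] = F.conv3_backward(
            dh, c2, params[f"{name}.conv2.W"]
        )
        dh = F.relu_backward(dh, r1)
        dh, grads[f"{name}.conv1.W"], grads[f"{name}.conv1.b"] = F.conv3_backward(
            dh, c1, params[f"{name}.conv1.W"]
        )
        return dh

    # -- inference ----------------------------------------------------------

    def predict_proba(self, params: dict, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
        """Per-pixel lung probabilities for a slice batch ``(n, 1, H, W)``."""
        outs = []
        for k in range(0, x.shape[0], batch_size):
            logits, _ = self.forward(params, x[k : k + batch_size], want_cache=False)
            outs.append(F.sigmoid(logits))
        return np.concatenate(outs, axis=0)
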