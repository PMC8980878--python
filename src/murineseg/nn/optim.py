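"""Adam optimizer over flat parameter dicts, with per-parameter freezing."""

from __future__ import annotations

import numpy as np

__all__ = ["Adam"]


class Adam:
    """Standard Adam (bias-corrected first/second moments).

    ``trainable`` is an optional predicate on parameter names; frozen
    parameters are left bitwise untouched — they are never even read by the
    update — which is what encoder-frozen transfer learning relies on.
    """

    def __init__(self, lr: float = 1e-4, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._m: dict[str, np.ndarray] = {}
        self._v: dict[str, np.ndarray] = {}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray], trainable=None) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1.0 - b1**self.t
        c2 = 1.0 - b2**self.t
        for name, g in grads.items():
            if trainable is not None and not trainable(name):
                continue
            m = self._m.setdefault(name, np.zeros_like(g))
            v = self._v.setdefault(name, np.zeros_like(g))
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            params[name] = params[name] - self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)
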