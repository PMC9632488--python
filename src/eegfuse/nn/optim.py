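"""Gradient-descent optimizers operating on a network's parameter dicts."""

from __future__ import annotations

import numpy as np


class SGD:
    def __init__(self, lr: float = 1e-4):
        self.lr = lr

    def step(self, layers) -> None:
        for layer in layers:
            for name in layer.param_names:
                getattr(layer, name)[...] -= self.lr * getattr(layer, "d_" + name)


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, lr: float = 1e-4, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._m: dict[tuple[int, str], np.ndarray] = {}
        self._v: dict[tuple[int, str], np.ndarray] = {}

    def step(self, layers) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for li, layer in enumerate(layers):
            for name in layer.param_names:
                key = (li, name)
                g = getattr(layer, "d_" + name)
                if key not in self._m:
                    self._m[key] = np.zeros_like(g)
                    self._v[key] = np.zeros_like(g)
                m = self._m[key]
                v = self._v[key]
                m *= self.beta1
                m += (1 - self.beta1) * g
                v *= self.beta2
                v += (1 - self.beta2) * g * g
                update = self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
                getattr(layer, name)[...] -= update


def make_optimizer(name: str, lr: float):
    if name == "adam":
        return Adam(lr=lr)
    if name == "sgd":
        return SGD(lr=lr)
    raise ValueError(f"unknown optimizer {name!r}")
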