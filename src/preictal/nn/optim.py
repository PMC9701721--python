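"""Adam optimizer over a list of (layer, parameter-name) handles."""

from __future__ import annotations

import numpy as np

__all__ = ["Adam"]


class Adam:
    def __init__(self, handles, lr: float = 3e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        if lr < 0:
            raise ValueError("learning rate must be non-negative")
        self.handles = list(handles)   # (layer, name) pairs
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(layer.params[name]) for layer, name in self.handles]
        self.v = [np.zeros_like(layer.params[name]) for layer, name in self.handles]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for k, (layer, name) in enumerate(self.handles):
            g = layer.grads[name]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * (g * g)
            mhat = self.m[k] / bc1
            vhat = self.v[k] / bc2
            layer.params[name] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
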