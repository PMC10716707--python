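"""AdamW optimizer (decoupled weight decay)."""

from __future__ import annotations

import numpy as np

from .core import Param


class AdamW:
    def __init__(self, params: list[tuple[str, Param]],
                 lr: float = 1e-4, weight_decay: float = 1e-5,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.weight_decay = lr, weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {name: np.zeros_like(p.value) for name, p in params}
        self.v = {name: np.zeros_like(p.value) for name, p in params}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for name, p in self.params:
            g = p.grad
            m = self.m[name]
            v = self.v[name]
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            update = (m / bias1) / (np.sqrt(v / bias2) + self.eps)
            p.value -= self.lr * (update + self.weight_decay * p.value)

    def zero_grad(self) -> None:
        for _, p in self.params:
            p.grad[...] = 0.0
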