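"""Adaptive-moment gradient descent (Adam)."""

from __future__ import annotations

import numpy as np

from .layers import Parameter


class Adam:
    """Adam with decay rates ``alpha1``/``alpha2`` for the first/second
    gradient moments and bias correction."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 alpha1: float = 0.9, alpha2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.alpha1, self.alpha2, self.eps = lr, alpha1, alpha2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1c = 1.0 - self.alpha1 ** self.t
        b2c = 1.0 - self.alpha2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.alpha1
            m += (1.0 - self.alpha1) * g
            v *= self.alpha2
            v += (1.0 - self.alpha2) * (g * g)
            p.data -= (self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)).astype(p.data.dtype)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
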