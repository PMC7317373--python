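"""Adam optimizer with L2 decay restricted to parameters flagged ``decay``
(convolution kernels)."""

from __future__ import annotations

import numpy as np

from .layers import DTYPE, Param


class Adam:
    def __init__(
        self,
        params: list[Param],
        lr: float = 1e-4,
        l2_weight: float = 0.0,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.l2_weight = l2_weight
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if p.decay and self.l2_weight:
                g = g + self.l2_weight * p.value
            m += (1.0 - self.beta1) * (g - m)
            v += (1.0 - self.beta2) * (g * g - v)
            p.value -= (self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)).astype(DTYPE)
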