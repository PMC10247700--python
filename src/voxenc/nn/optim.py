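"""Adam optimizer for :class:`voxenc.nn.layers.Param` objects."""

from __future__ import annotations

import numpy as np

from .layers import Param


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.v) for p in self.params]
        self.s = [np.zeros_like(p.v) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, s in zip(self.params, self.m, self.s):
            if p.frozen:
                continue
            m[...] = self.b1 * m + (1.0 - self.b1) * p.g
            s[...] = self.b2 * s + (1.0 - self.b2) * p.g ** 2
            p.v -= self.lr * (m / b1t) / (np.sqrt(s / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
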