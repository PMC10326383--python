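"""Optimizers (Adam only — the stack needs nothing else)."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.5, 0.9), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self, grads: list[Tensor | np.ndarray]):
        if len(grads) != len(self.params):
            raise ValueError("gradient list does not match parameter list")
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for i, (p, g) in enumerate(zip(self.params, grads)):
            ga = g.data if isinstance(g, Tensor) else np.asarray(g)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * ga
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * ga * ga
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
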