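"""Stochastic gradient descent with classical momentum and decoupled-by-flag
L2 weight decay (applied only to parameters whose ``decay`` attribute is true,
i.e. conv/linear weights but not batch-norm scales or biases)."""

from __future__ import annotations

import numpy as np

from .layers import Parameter


class SGD:
    def __init__(self, params, lr: float, momentum: float = 0.0,
                 weight_decay: float = 0.0):
        self.params: list[Parameter] = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay and getattr(p, "decay", False):
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
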