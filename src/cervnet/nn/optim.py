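"""Stochastic gradient descent with (Nesterov) momentum and weight decay.

Matches the common deep-learning convention: the decayed gradient
g = grad + wd·w enters the momentum buffer b ← m·b + g, and the update
direction is g + m·b under Nesterov, or b for classical momentum.
"""

from __future__ import annotations

from typing import Iterable, List

import numpy as np

from .core import Parameter

__all__ = ["SGD"]


class SGD:
    def __init__(self, params: Iterable[Parameter], lr: float, momentum: float = 0.9,
                 weight_decay: float = 1e-4, nesterov: bool = True):
        self.params: List[Parameter] = list(params)
        if lr <= 0:
            raise ValueError("lr must be positive")
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.nesterov = nesterov
        self._buffers = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, buf in zip(self.params, self._buffers):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            buf *= self.momentum
            buf += g
            d = g + self.momentum * buf if self.nesterov else buf
            p.data -= self.lr * d

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0
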