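"""Optimizers. AdamW with decoupled weight decay is the only one the
training loops use."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = ["AdamW"]


class AdamW:
    """Adam with decoupled weight decay.

    Decay is applied directly to the weights (``w -= lr * wd * w``) rather
    than folded into the gradient, so it is independent of the adaptive
    step scaling.
    """

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.01):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
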