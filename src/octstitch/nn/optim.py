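"""Optimizers and learning-rate schedules for backbone training."""
from __future__ import annotations

import math

import numpy as np

from .autograd import DTYPE
from .layers import Parameter


class AdamW:
    """Adam with decoupled weight decay.

    Parameters whose gradient is ``None`` at step time are left untouched,
    including their moment estimates — this is what lets random-path
    training of a stitching space update only the active path.
    """

    def __init__(self, params: list[Parameter], lr: float = 5e-5,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.01):
        self.params = list(params)
        self.lr = float(lr)
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._t = [0] * len(self.params)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self._t[i] += 1
            t = self._t[i]
            self._m[i] = b1 * self._m[i] + (1 - b1) * g
            self._v[i] = b2 * self._v[i] + (1 - b2) * g * g
            mhat = self._m[i] / (1 - b1 ** t)
            vhat = self._v[i] / (1 - b2 ** t)
            p.data -= (self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                                  + self.weight_decay * p.data)).astype(DTYPE)


class StepLR:
    """Multiply the learning rate by `gamma` at the given epoch milestones."""

    def __init__(self, optimizer: AdamW, milestones: list[int],
                 gamma: float = 0.1):
        self.optimizer = optimizer
        self.milestones = sorted(milestones)
        self.gamma = gamma
        self.base_lr = optimizer.lr
        self.last_epoch = 0

    def step(self) -> None:
        self.last_epoch += 1
        n = sum(1 for m in self.milestones if self.last_epoch >= m)
        self.optimizer.lr = self.base_lr * self.gamma ** n


class CosineAnnealingLR:
    """Cosine decay from the base rate to `eta_min` over `t_max` steps."""

    def __init__(self, optimizer: AdamW, t_max: int, eta_min: float = 0.0):
        self.optimizer = optimizer
        self.t_max = max(int(t_max), 1)
        self.eta_min = eta_min
        self.base_lr = optimizer.lr
        self.last_step = 0

    def step(self) -> None:
        self.last_step = min(self.last_step + 1, self.t_max)
        cos = 0.5 * (1 + math.cos(math.pi * self.last_step / self.t_max))
        self.optimizer.lr = self.eta_min + (self.base_lr - self.eta_min) * cos
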