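"""Optimizers and learning-rate schedules."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = ["Adam", "StepDecay"]


class Adam:
    """Adam with bias correction; parameters with no gradient are skipped."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * p.grad**2
            m_hat = m / (1 - self.beta1**self.t)
            v_hat = v / (1 - self.beta2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


class StepDecay:
    """Multiply the optimizer's learning rate by ``factor`` every ``every`` epochs."""

    def __init__(self, optimizer: Adam, every: int = 500, factor: float = 0.2):
        self.optimizer = optimizer
        self.every = every
        self.factor = factor
        self.epoch = 0

    def step(self) -> None:
        self.epoch += 1
        if self.every > 0 and self.epoch % self.every == 0:
            self.optimizer.lr *= self.factor
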