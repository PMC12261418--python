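"""Optimizers and learning-rate schedules."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = ["Adam", "cosine_annealing_lr"]


def cosine_annealing_lr(initial_lr: float, step: int, total_steps: int) -> float:
    """Cosine annealing from `initial_lr` down to 0 over `total_steps`."""
    if total_steps <= 1:
        return initial_lr
    frac = min(step, total_steps - 1) / (total_steps - 1)
    return initial_lr * 0.5 * (1.0 + np.cos(np.pi * frac))


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
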