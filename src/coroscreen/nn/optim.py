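"""Optimizers and the cosine learning-rate schedule."""

from __future__ import annotations

import numpy as np

__all__ = ["cosine_lr", "RMSprop", "Adam"]


def cosine_lr(epoch: int, total_epochs: int, lr0: float = 0.001) -> float:
    """Cosine annealing: lr0 * (1 + cos(pi * epoch / total)) / 2.

    Starts at lr0 and anneals to 0 at ``total_epochs``.
    """
    if not 0 <= epoch <= total_epochs:
        raise ValueError(f"epoch must be in [0, {total_epochs}], got {epoch}")
    return lr0 * (1.0 + np.cos(np.pi * epoch / total_epochs)) / 2.0


class RMSprop:
    """Momentum-free adaptive optimizer (default for training)."""

    def __init__(self, model, rho: float = 0.9, eps: float = 1e-8, weight_decay: float = 0.0):
        self.model = model
        self.rho, self.eps, self.weight_decay = rho, eps, weight_decay
        self.cache: dict = {}

    def step(self, lr: float) -> None:
        for name, p, g in self.model.parameters():
            if self.weight_decay and p.ndim > 1:
                g = g + self.weight_decay * p
            c = self.cache.get(name)
            if c is None:
                c = np.zeros_like(p)
            c[...] = self.rho * c + (1 - self.rho) * g * g
            self.cache[name] = c
            p -= (lr * g / (np.sqrt(c) + self.eps)).astype(p.dtype)


class Adam:
    def __init__(self, model, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.model = model
        self.beta1, self.beta2, self.eps, self.weight_decay = beta1, beta2, eps, weight_decay
        self.m: dict = {}
        self.v: dict = {}
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for name, p, g in self.model.parameters():
            if self.weight_decay and p.ndim > 1:
                g = g + self.weight_decay * p
            m = self.m.setdefault(name, np.zeros_like(p))
            v = self.v.setdefault(name, np.zeros_like(p))
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= (lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)
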