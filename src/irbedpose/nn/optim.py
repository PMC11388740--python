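"""Optimizers and learning-rate schedules."""

from __future__ import annotations

import numpy as np

__all__ = ["AdamW", "OneCycleLR", "ExponentialLR"]


class AdamW:
    """AdamW with decoupled weight decay (Loshchilov & Hutter)."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 1e-4):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class OneCycleLR:
    """One-cycle policy: linear warm-up to max_lr, cosine anneal to ~0."""

    def __init__(self, optimizer: AdamW, max_lr: float, total_steps: int,
                 pct_start: float = 0.3, div_factor: float = 25.0,
                 final_div_factor: float = 1e3):
        self.opt = optimizer
        self.max_lr = max_lr
        self.total = max(int(total_steps), 1)
        self.warm = max(int(round(pct_start * self.total)), 1)
        self.lr0 = max_lr / div_factor
        self.lr_end = max_lr / final_div_factor
        self.step_num = 0
        self.opt.lr = self.lr0

    def step(self):
        self.step_num += 1
        s = self.step_num
        if s <= self.warm:
            lr = self.lr0 + (self.max_lr - self.lr0) * s / self.warm
        else:
            frac = min((s - self.warm) / max(self.total - self.warm, 1), 1.0)
            lr = self.lr_end + 0.5 * (self.max_lr - self.lr_end) * \
                (1 + np.cos(np.pi * frac))
        self.opt.lr = float(lr)


class ExponentialLR:
    """Per-epoch decay: lr <- lr0 * gamma^epoch."""

    def __init__(self, optimizer: AdamW, gamma: float = 0.9):
        self.opt = optimizer
        self.gamma = gamma
        self.lr0 = optimizer.lr
        self.epoch = 0

    def step(self):
        self.epoch += 1
        self.opt.lr = self.lr0 * self.gamma ** self.epoch
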