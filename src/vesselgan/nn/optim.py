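"""Gradient-based optimizers: Adam and RMSProp with momentum.

Both keep per-parameter state arrays and support a mutable learning rate so
an exponential per-epoch schedule can be applied from outside.
"""

from __future__ import annotations

import numpy as np

_F32 = np.float32


class Optimizer:
    def __init__(self, params, lr: float):
        self.params = list(params)
        self.lr = float(lr)

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):  # pragma: no cover - abstract
        raise NotImplementedError


class Adam(Optimizer):
    def __init__(self, params, lr=2e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        super().__init__(params, lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= _F32(self.lr) * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


class RMSProp(Optimizer):
    """RMSProp with a momentum buffer (the common TF formulation)."""

    def __init__(self, params, lr=2e-4, rho=0.9, momentum=0.9, eps=1e-8):
        super().__init__(params, lr)
        self.rho, self.momentum, self.eps = rho, momentum, eps
        self.sq = [np.zeros_like(p.data) for p in self.params]
        self.buf = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, sq, buf in zip(self.params, self.sq, self.buf):
            if p.grad is None:
                continue
            g = p.grad
            sq *= self.rho
            sq += (1 - self.rho) * g * g
            buf *= self.momentum
            buf += _F32(self.lr) * g / (np.sqrt(sq) + self.eps)
            p.data -= buf
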