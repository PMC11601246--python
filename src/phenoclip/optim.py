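"""Optimizers. Only RAdam (rectified Adam) is provided, matching the
training recipe: Adam with a variance-rectification term that falls back to
plain SGD-with-momentum steps while the second-moment estimate is unreliable.
"""

from __future__ import annotations

import numpy as np

__all__ = ["RAdam"]


class RAdam:
    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.rho_inf = 2.0 / (1.0 - self.b2) - 1.0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        t = self.t
        b1, b2 = self.b1, self.b2
        rho_t = self.rho_inf - 2.0 * t * b2 ** t / (1.0 - b2 ** t)
        bias1 = 1.0 - b1 ** t
        if rho_t > 4.0:
            r = np.sqrt(((rho_t - 4.0) * (rho_t - 2.0) * self.rho_inf)
                        / ((self.rho_inf - 4.0) * (self.rho_inf - 2.0) * rho_t))
            bias2 = 1.0 - b2 ** t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            m_hat = m / bias1
            if rho_t > 4.0:
                step = self.lr * r * m_hat / (np.sqrt(v / bias2) + self.eps)
            else:
                step = self.lr * m_hat
            p.data -= step.astype(p.data.dtype)
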