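"""Optimizers, gradient clipping and the polynomial learning-rate schedule."""

from __future__ import annotations

import numpy as np

from .layers import Param

__all__ = ["SGDNesterov", "Adam", "clip_grad_norm", "polynomial_lr"]


def clip_grad_norm(params: list[Param], max_norm: float) -> float:
    """Clip the global L2 norm of all gradients to ``max_norm``.

    Returns the pre-clip norm.
    """
    total = 0.0
    for p in params:
        total += float(np.sum(p.grad.astype(np.float64) ** 2))
    norm = float(np.sqrt(total))
    if norm > max_norm > 0:
        scale = np.float32(max_norm / (norm + 1e-12))
        for p in params:
            p.grad *= scale
    return norm


def polynomial_lr(step: int, total_steps: int, lr_start: float, lr_end: float,
                  power: float = 1.0) -> float:
    """lr(t) = (lr_start - lr_end) * (1 - t/T)^p + lr_end, lr(T) = lr_end."""
    if total_steps <= 0:
        return lr_start
    t = min(max(step, 0), total_steps)
    frac = 1.0 - t / total_steps
    return (lr_start - lr_end) * frac ** power + lr_end


class _Optimizer:
    def __init__(self, params: list[Param]):
        self.params = params

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0

    def step(self, lr: float) -> None:
        raise NotImplementedError


class SGDNesterov(_Optimizer):
    """SGD with Nesterov momentum (velocity formulation).

    v <- mu*v + g;  theta <- theta - lr * (g + mu*v)
    """

    def __init__(self, params: list[Param], momentum: float = 0.99):
        super().__init__(params)
        self.momentum = momentum
        self.velocity = [np.zeros_like(p.value) for p in params]

    def step(self, lr: float) -> None:
        mu = np.float32(self.momentum)
        for p, v in zip(self.params, self.velocity):
            v *= mu
            v += p.grad
            p.value -= np.float32(lr) * (p.grad + mu * v)


class Adam(_Optimizer):
    def __init__(self, params: list[Param], betas=(0.9, 0.999), eps: float = 1e-8):
        super().__init__(params)
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * (p.grad * p.grad)
            p.value -= np.float32(lr) * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
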