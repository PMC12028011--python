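"""Adam optimizer and L1/L2 weight penalties.

The penalties are part of the minimized objective
``BCE + l1 * sum(|w|) + l2 * sum(w^2)`` over weight parameters only
(biases and batch-norm affines are exempt); they are applied by adding
their analytic gradient before the Adam step.
"""

from __future__ import annotations

import numpy as np

from bpfuse.nn.layers import Module, Parameter

__all__ = ["Adam", "apply_weight_penalties", "weight_penalty_value"]


def weight_penalty_value(model: Module, l1: float, l2: float) -> float:
    """Value of ``l1 * sum(|w|) + l2 * sum(w^2)`` over weight parameters."""
    if l1 == 0 and l2 == 0:
        return 0.0
    total = 0.0
    for p in model.parameters():
        if getattr(p, "is_weight", False):
            total += l1 * np.abs(p.data).sum() + l2 * (p.data**2).sum()
    return float(total)


def apply_weight_penalties(model: Module, l1: float, l2: float) -> None:
    """Add d/dw of the L1/L2 penalties to existing gradients in place."""
    if l1 == 0 and l2 == 0:
        return
    for p in model.parameters():
        if getattr(p, "is_weight", False) and p.grad is not None:
            p.grad += l1 * np.sign(p.data) + 2.0 * l2 * p.data


class Adam:
    def __init__(self, params: list[Parameter], lr: float = 3e-5,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        if lr < 0:
            raise ValueError("lr must be non-negative")
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
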