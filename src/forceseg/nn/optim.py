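"""Adam optimizer with parameter groups.

The scale weights of the multi-scale aggregator train in their own group at
a reduced learning rate (0.1 × base) with weight decay 1e-4, keeping the
softmax-normalized fusion stable; all other parameters use the base rate.
Weight decay is applied L2-style (added to the gradient before the moment
updates).
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = ["Adam"]


class Adam:
    def __init__(self, param_groups: list[dict], beta1=0.9, beta2=0.999, eps=1e-8):
        # each group: {"params": [...], "lr": float, "weight_decay": float}
        self.groups = param_groups
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.state = {}
        for g in self.groups:
            for p in g["params"]:
                self.state[id(p)] = (np.zeros_like(p.data), np.zeros_like(p.data))

    def set_lr(self, base_lr: float) -> None:
        """Rescale every group's lr, preserving its ratio to the base rate."""
        for g in self.groups:
            g["lr"] = base_lr * g.get("lr_scale", 1.0)

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1**self.t
        bc2 = 1 - b2**self.t
        for g in self.groups:
            lr, wd = g["lr"], g.get("weight_decay", 0.0)
            for p in g["params"]:
                if p.grad is None:
                    continue
                grad = p.grad + wd * p.data if wd else p.grad
                m, v = self.state[id(p)]
                m *= b1
                m += (1 - b1) * grad
                v *= b2
                v += (1 - b2) * grad * grad
                p.data -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for g in self.groups:
            for p in g["params"]:
                p.grad = None
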