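"""Adam optimizer with parameter groups (needed for layer-wise LR decay)."""

from __future__ import annotations

import numpy as np

from .layers import Parameter


class Adam:
    def __init__(self, param_groups, lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        # accept either a flat list of parameters or [{'params': [...], 'lr': ...}]
        if param_groups and isinstance(param_groups[0], Parameter):
            param_groups = [{"params": list(param_groups)}]
        self.groups = []
        for group in param_groups:
            g = {"params": list(group["params"]),
                 "lr": float(group.get("lr", lr))}
            self.groups.append(g)
        self.betas = betas
        self.eps = eps
        self.t = 0
        self._m = {}
        self._v = {}

    def set_lr(self, lr: float, scale_groups: bool = False) -> None:
        """Set a global LR; with ``scale_groups`` each group keeps its ratio
        to the first group (used for LLRD under a decaying schedule)."""
        if scale_groups and self.groups:
            base = self.groups[0]["lr"]
            for g in self.groups:
                ratio = g["lr"] / base if base > 0 else 1.0
                g["lr"] = lr * ratio
        else:
            for g in self.groups:
                g["lr"] = lr

    def step(self) -> None:
        b1, b2 = self.betas
        self.t += 1
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for group in self.groups:
            lr = group["lr"]
            for p in group["params"]:
                if p.grad is None:
                    continue
                key = id(p)
                grad = np.asarray(p.grad, dtype=np.float64)
                m = self._m.get(key)
                v = self._v.get(key)
                if m is None:
                    m = np.zeros_like(grad)
                    v = np.zeros_like(grad)
                m = b1 * m + (1 - b1) * grad
                v = b2 * v + (1 - b2) * grad * grad
                self._m[key] = m
                self._v[key] = v
                update = lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
                p.data = p.data - update.astype(p.data.dtype)

    def zero_grad(self) -> None:
        for group in self.groups:
            for p in group["params"]:
                p.grad = None
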