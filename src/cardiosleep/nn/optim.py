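"""Adam optimizer and binary cross-entropy losses."""

from __future__ import annotations

import numpy as np

from .layers import Param

__all__ = ["Adam", "bce_with_logits"]


class Adam:
    """Adam with classic (coupled) weight decay applied to kernel weights."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 weight_decay: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for i, p in enumerate(self.params):
            g = p.grad
            if self.weight_decay and p.is_kernel:
                g = g + self.weight_decay * p.value
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / bc1
            vhat = self.v[i] / bc2
            p.value -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                p.value.dtype
            )


def bce_with_logits(z: np.ndarray, y: np.ndarray, weights: np.ndarray | None = None):
    """Numerically stable binary cross-entropy on logits.

    Returns ``(mean_loss, dloss/dz)``.  ``weights`` are per-element sample
    weights; the loss is the plain mean of the weighted elementwise terms
    so the gradient scale matches common framework semantics.
    """
    z = np.asarray(z, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    elem = np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))
    sig = 1.0 / (1.0 + np.exp(-z))
    dz = sig - y
    if weights is not None:
        elem = elem * weights
        dz = dz * weights
    n = z.size
    return float(elem.sum() / n), dz / n
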