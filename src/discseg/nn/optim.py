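"""Adam optimizer over :class:`~discseg.nn.layers.Param` lists."""

from __future__ import annotations

import numpy as np

from .layers import Param


class Adam:
    """Adam with the standard bias-corrected first/second moment estimates."""

    def __init__(
        self,
        params: list[Param],
        learning_rate: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        if learning_rate < 0:
            raise ValueError("learning rate must be >= 0")
        self.params = params
        self.lr = learning_rate
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * p.grad
            v *= self.beta2
            v += (1.0 - self.beta2) * np.square(p.grad)
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
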