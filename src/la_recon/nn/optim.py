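"""ADAM optimizer for the numpy layer library."""

from __future__ import annotations

import numpy as np

from .layers import Param


class Adam:
    """Adaptive moment estimation with bias-corrected moments."""

    def __init__(
        self,
        params: list[Param],
        learning_rate: float = 1e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        if not 0 < beta1 < beta2 < 1:
            raise ValueError(f"need 0 < beta1 < beta2 < 1, got {beta1}, {beta2}")
        if learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        self.params = params
        self.lr = learning_rate
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
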