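"""Adam optimiser with decoupled selection of weight-decay parameters."""

from __future__ import annotations

import numpy as np

from .layers import Parameter


class Adam:
    """Adam with L2 regularisation added to the gradient.

    Weight decay is applied only to parameters flagged ``decay=True``
    (convolution and linear weights); batch-norm scales/shifts and biases
    are left unregularised.
    """

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999,
                 weight_decay: float = 0.0, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.weight_decay = weight_decay
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]
        self._v = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad.astype(np.float64)
            if self.weight_decay and p.decay:
                g = g + self.weight_decay * p.data.astype(np.float64)
            m += (1.0 - b1) * (g - m)
            v += (1.0 - b2) * (g * g - v)
            update = self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
            p.data -= update.astype(p.data.dtype)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
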