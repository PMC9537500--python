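"""Optimisers. SGD with optional momentum and per-step learning-rate decay.

The decay follows the classic schedule ``lr_t = lr0 / (1 + decay * t)`` with
``t`` counted in update steps.
"""

from __future__ import annotations

import numpy as np

from .network import Sequential

__all__ = ["SGD"]


class SGD:
    def __init__(self, net: Sequential, lr: float, momentum: float = 0.0, decay: float = 0.0):
        self.net = net
        self.lr0 = lr
        self.momentum = momentum
        self.decay = decay
        self.t = 0
        self._velocity: dict[tuple[int, str], np.ndarray] = {}

    @property
    def lr(self) -> float:
        return self.lr0 / (1.0 + self.decay * self.t)

    def step(self) -> None:
        lr = self.lr
        for i, layer in enumerate(self.net.layers):
            for key, grad in layer.grads.items():
                param = layer.params[key]
                if self.momentum:
                    v = self._velocity.setdefault((i, key), np.zeros_like(param))
                    v *= self.momentum
                    v -= lr * grad
                    param += v
                else:
                    param -= lr * grad
        self.t += 1

    def zero_grad(self) -> None:
        for layer in self.net.layers:
            layer.grads = {}
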