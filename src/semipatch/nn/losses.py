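"""Loss functions paired with the gradients their backward passes need.

The networks in this package end in explicit Softmax / Sigmoid layers (the
output is a class-membership probability), so losses are defined on
probabilities with a clipping floor for numerical safety.
"""

from __future__ import annotations

import numpy as np

_EPS = 1e-12

__all__ = ["nll_loss", "bce_loss"]


def nll_loss(probs: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean negative log-likelihood of integer labels under row probabilities.

    Returns (loss, d_loss/d_probs).
    """
    n = probs.shape[0]
    p = np.clip(probs, _EPS, 1.0)
    loss = -np.log(p[np.arange(n), y]).mean()
    grad = np.zeros_like(probs)
    grad[np.arange(n), y] = -1.0 / (p[np.arange(n), y] * n)
    return float(loss), grad


def bce_loss(probs: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy between probabilities and 0/1 targets."""
    p = np.clip(probs, _EPS, 1.0 - _EPS)
    loss = -(target * np.log(p) + (1.0 - target) * np.log(1.0 - p)).mean()
    grad = (-(target / p) + (1.0 - target) / (1.0 - p)) / p.size
    return float(loss), grad
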