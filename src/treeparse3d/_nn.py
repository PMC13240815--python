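"""Minimal NumPy neural-network primitives shared by the encoder blocks.

Weights are created once from a seeded generator and are deterministic
thereafter; forward passes contain no randomness.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit


def sigmoid(x: np.ndarray) -> np.ndarray:
    return expit(x)


def softplus(x: np.ndarray) -> np.ndarray:
    # ln(1 + e^x), overflow-safe
    return np.logaddexp(0.0, x)


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - np.max(x, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=axis, keepdims=True)


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


class Linear:
    """Dense layer y = x @ W + b with Glorot-uniform init."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (d_in + d_out))
        self.W = rng.uniform(-limit, limit, size=(d_in, d_out))
        self.b = np.zeros(d_out)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return x @ self.W + self.b

    def zero_(self) -> "Linear":
        self.W[:] = 0.0
        self.b[:] = 0.0
        return self

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size


class MLP:
    """2-layer perceptron (hidden width = 2x input by convention here)."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 hidden: int | None = None, activation: str = "relu"):
        hidden = hidden if hidden is not None else 2 * d_in
        self.l1 = Linear(d_in, hidden, rng)
        self.l2 = Linear(hidden, d_out, rng)
        self.activation = activation

    def __call__(self, x: np.ndarray) -> np.ndarray:
        h = self.l1(x)
        h = relu(h) if self.activation == "relu" else np.tanh(h)
        return self.l2(h)

    def zero_(self) -> "MLP":
        self.l1.zero_()
        self.l2.zero_()
        return self

    @property
    def n_params(self) -> int:
        return self.l1.n_params + self.l2.n_params
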