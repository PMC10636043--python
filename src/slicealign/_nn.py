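"""Minimal fully-connected networks with explicit forward/backward passes.

Deliberately tiny: two-layer perceptrons with LeakyReLU, full-batch Adam,
and hand-written gradients.  The alignment model works at desk scale
(thousands of cells, widths <= a few thousand), where dense NumPy matmuls
are fast and bit-reproducible given a fixed seed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MLP", "Adam", "leaky_relu"]


def leaky_relu(x: np.ndarray, slope: float = 0.2) -> np.ndarray:
    return np.where(x >= 0, x, slope * x)


class MLP:
    """Two-layer perceptron ``in -> hidden -> out`` with LeakyReLU.

    ``forward`` optionally records a cache for ``backward``; ``backward``
    accumulates parameter gradients (call ``zero_grad`` between steps) and
    returns the gradient with respect to the input.
    """

    def __init__(
        self,
        d_in: int,
        d_hidden: int,
        d_out: int,
        rng: np.random.Generator,
        slope: float = 0.2,
        dtype=np.float32,
    ):
        self.slope = slope
        self.dtype = dtype
        # He-style init adjusted for LeakyReLU gain
        gain = np.sqrt(2.0 / (1.0 + slope**2))
        s1 = gain / np.sqrt(d_in)
        s2 = gain / np.sqrt(d_hidden)
        self.W1 = (rng.standard_normal((d_in, d_hidden)) * s1).astype(dtype)
        self.b1 = np.zeros(d_hidden, dtype=dtype)
        self.W2 = (rng.standard_normal((d_hidden, d_out)) * s2).astype(dtype)
        self.b2 = np.zeros(d_out, dtype=dtype)
        self.zero_grad()

    # -- parameter plumbing -------------------------------------------------
    def params(self) -> list[np.ndarray]:
        return [self.W1, self.b1, self.W2, self.b2]

    def grads(self) -> list[np.ndarray]:
        return [self.gW1, self.gb1, self.gW2, self.gb2]

    def zero_grad(self) -> None:
        self.gW1 = np.zeros_like(self.W1)
        self.gb1 = np.zeros_like(self.b1)
        self.gW2 = np.zeros_like(self.W2)
        self.gb2 = np.zeros_like(self.b2)

    def clip_weights(self, c: float) -> None:
        for p in self.params():
            np.clip(p, -c, c, out=p)

    # -- forward / backward -------------------------------------------------
    def forward(self, X: np.ndarray, cache: dict | None = None) -> np.ndarray:
        X = X.astype(self.dtype, copy=False)
        H = X @ self.W1 + self.b1
        Hp = leaky_relu(H, self.slope)
        Y = Hp @ self.W2 + self.b2
        if cache is not None:
            cache["X"], cache["H"], cache["Hp"] = X, H, Hp
        return Y

    def backward(self, dY: np.ndarray, cache: dict) -> np.ndarray:
        """Accumulate parameter grads for output grad ``dY``; return dX."""
        X, H, Hp = cache["X"], cache["H"], cache["Hp"]
        dY = dY.astype(self.dtype, copy=False)
        self.gW2 += Hp.T @ dY
        self.gb2 += dY.sum(axis=0)
        dHp = dY @ self.W2.T
        dH = np.where(H >= 0, dHp, self.slope * dHp)
        self.gW1 += X.T @ dH
        self.gb1 += dH.sum(axis=0)
        return dH @ self.W1.T


class Adam:
    """Standard Adam with bias correction, one parameter list per instance."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
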