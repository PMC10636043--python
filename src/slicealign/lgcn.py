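"""Lightweight graph convolution: parameter-free multi-scale cell features.

The holistic representation concatenates the node features with their
repeated propagations through the normalised adjacency::

    X~ = Concat(X, A_hat X, A_hat^2 X, ..., A_hat^L X)

Block 0 is the cell's own (molecular) embedding, block 1 summarises its
immediate spatial neighbourhood (microenvironment), and higher blocks
coarsen towards rough position within the tissue.  There are no learned
weights and no nonlinearity; powers of A_hat are never materialised —
propagation is L sparse matrix products.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .graph import SpatialGraph
from .preprocess import EmbeddingPair

__all__ = ["HolisticRepresentation", "lgcn_forward", "holistic_pair"]


@dataclass
class HolisticRepresentation:
    """Concatenated propagation blocks, shape ``(N, (L+1) * M)``."""

    Xt: np.ndarray
    L: int
    M: int

    def __post_init__(self) -> None:
        if self.Xt.shape[1] != (self.L + 1) * self.M:
            raise ValueError("Xt width inconsistent with L and M")

    @property
    def n(self) -> int:
        return self.Xt.shape[0]

    @property
    def blocks(self) -> list[np.ndarray]:
        """Views of the L+1 M-wide column blocks (block 0 = input X)."""
        return [self.Xt[:, l * self.M : (l + 1) * self.M] for l in range(self.L + 1)]


def lgcn_forward(A_hat: sp.spmatrix, X: np.ndarray, L: int) -> HolisticRepresentation:
    """Propagate X through A_hat L times and concatenate all depths."""
    if L < 0:
        raise ValueError("L must be >= 0")
    X = np.asarray(X, dtype=float)
    if A_hat.shape[0] != X.shape[0]:
        raise ValueError(
            f"operator is {A_hat.shape} but features have {X.shape[0]} rows"
        )
    blocks = [X]
    H = X
    for _ in range(L):
        H = A_hat @ H
        blocks.append(H)
    return HolisticRepresentation(np.ascontiguousarray(np.hstack(blocks)), L, X.shape[1])


def holistic_pair(
    ep: EmbeddingPair, g1: SpatialGraph, g2: SpatialGraph, L: int = 3
) -> tuple[HolisticRepresentation, HolisticRepresentation]:
    """Apply the LGCN independently per slice with a shared depth L.

    ``L = 0`` disables spatial propagation entirely (the "no LGCN"
    ablation): matching then relies on per-cell molecular features alone.
    """
    if g1.n != ep.X1.shape[0] or g2.n != ep.X2.shape[0]:
        raise ValueError("graph size does not match embedding rows")
    return lgcn_forward(g1.A_hat, ep.X1, L), lgcn_forward(g2.A_hat, ep.X2, L)
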