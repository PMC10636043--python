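"""Batch-corrected shared embeddings for a pair of slices.

The two slices are reduced to a common low-dimensional space by a
cross-dataset SVD: with log-normalised, scaled matrices ``G1t`` (N1 x G)
and ``G2t`` (N2 x G) over shared features, the product ``G1t @ G2t.T`` is
factorised as ``U S V^T`` and each slice receives ``sqrt(S)``-weighted
singular vectors::

    X1 = U[:, :M] * sqrt(S[:M]),   X2 = V[:, :M] * sqrt(S[:M])

so that ``X1 @ X2.T`` is the Frobenius-optimal rank-M truncation of the
cross-product.  Correlated structure shared by both datasets dominates the
leading components, which suppresses dataset-specific (batch) variation.
Precomputed external embeddings (e.g. from a dedicated cross-modality
integration tool) can be passed through unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .io import SpatialSlice

__all__ = ["EmbeddingPair", "lognorm_scale", "shared_features", "svd_embed", "embed_pair"]


@dataclass
class EmbeddingPair:
    """Low-dimensional node features of the two slices (same width M)."""

    X1: np.ndarray
    X2: np.ndarray
    provenance: str = "svd"  # {"svd", "external"}

    def __post_init__(self) -> None:
        self.X1 = np.asarray(self.X1, dtype=float)
        self.X2 = np.asarray(self.X2, dtype=float)
        if self.X1.shape[1] != self.X2.shape[1]:
            raise ValueError("X1 and X2 must have the same number of columns")
        if not (np.isfinite(self.X1).all() and np.isfinite(self.X2).all()):
            raise ValueError("embeddings contain non-finite values")

    @property
    def M(self) -> int:
        return self.X1.shape[1]


def lognorm_scale(
    s: SpatialSlice,
    target_sum: float = 1e4,
    scale_clip: float = 10.0,
) -> np.ndarray:
    """Library-size normalise, log1p, then z-score each feature.

    Each cell is scaled to ``target_sum`` total counts, ``log1p`` is applied,
    and every feature is centred to mean 0 / unit variance using the
    population (n) denominator.  Zero-variance features are set to 0 and
    scaled values are clipped at ``+-scale_clip`` to guard outlier spots.

    Raises on all-zero cells; filter them first (``SpatialSlice.filter_cells``).
    """
    if s.is_embedding:
        raise ValueError("lognorm_scale expects raw counts, not embeddings")
    x = s.counts_dense().astype(float)
    totals = x.sum(axis=1)
    if np.any(totals <= 0):
        raise ValueError(
            f"{int((totals <= 0).sum())} all-zero cells; apply filter_cells first"
        )
    x = x * (target_sum / totals)[:, None]
    x = np.log1p(x)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)  # ddof=0: population denominator
    sd[sd == 0] = 1.0
    x = (x - mu) / sd
    np.clip(x, -scale_clip, scale_clip, out=x)
    return x


def shared_features(s1: SpatialSlice, s2: SpatialSlice) -> tuple[SpatialSlice, SpatialSlice]:
    """Restrict both slices to their overlapping features, same column order.

    The intersection is ordered by slice-1's feature order.
    """
    common = [n for n in s1.feature_names if n in set(s2.feature_names)]
    if not common:
        raise ValueError(
            "no overlapping features between the slices; for disjoint feature "
            "spaces provide precomputed embeddings (is_embedding=True)"
        )
    return s1.select_features(common), s2.select_features(common)


def svd_embed(G1t: np.ndarray, G2t: np.ndarray, M: int = 30) -> EmbeddingPair:
    """Truncated SVD of the cross-product ``G1t @ G2t.T`` without forming it.

    Both matrices are QR-factorised (``Gi = Qi Ri``), the SVD is computed on
    the small core ``R1 @ R2.T`` and the orthogonal factors are mapped back,
    which is exact and avoids the N1 x N2 dense product.  Sign ambiguity is
    resolved by making the largest-magnitude entry of each left singular
    vector positive (flipping the right vector jointly), so repeated calls
    are bit-identical.
    """
    G1t = np.asarray(G1t, dtype=float)
    G2t = np.asarray(G2t, dtype=float)
    if G1t.shape[1] != G2t.shape[1]:
        raise ValueError("feature dimension mismatch")
    Q1, R1 = np.linalg.qr(G1t)
    Q2, R2 = np.linalg.qr(G2t)
    Ub, svals, Vbt = np.linalg.svd(R1 @ R2.T, full_matrices=False)
    rank = int(np.sum(svals > svals[0] * 1e-12)) if svals.size else 0
    if M > rank:
        warnings.warn(
            f"requested M={M} exceeds numerical rank {rank}; shrinking", stacklevel=2
        )
        M = max(rank, 1)
    U = Q1 @ Ub[:, :M]
    V = Q2 @ Vbt[:M].T
    # deterministic sign convention
    for k in range(M):
        j = int(np.argmax(np.abs(U[:, k])))
        if U[j, k] < 0:
            U[:, k] *= -1
            V[:, k] *= -1
    w = np.sqrt(svals[:M])
    return EmbeddingPair(U * w, V * w, provenance="svd")


def _hvg_subset(x1: np.ndarray, x2: np.ndarray, n_top: int) -> np.ndarray:
    """Indices of the n_top features by pooled log1p-CPM variance."""
    v = np.var(x1, axis=0) + np.var(x2, axis=0)
    return np.sort(np.argsort(-v, kind="stable")[:n_top])


def embed_pair(
    s1: SpatialSlice,
    s2: SpatialSlice,
    M: int = 30,
    target_sum: float = 1e4,
    scale_clip: float = 10.0,
    hvg: int = 0,
) -> EmbeddingPair:
    """Full preprocessing: shared features -> lognorm/scale -> cross SVD.

    If both slices carry precomputed embeddings they are passed through with
    ``provenance="external"``; mixing counts with embeddings is an error.
    Optional ``hvg > 0`` restricts the SVD to the most variable shared
    features (off by default; the core path uses the full scaled matrices).
    """
    if s1.is_embedding or s2.is_embedding:
        if not (s1.is_embedding and s2.is_embedding):
            raise ValueError("cannot mix count input with precomputed embeddings")
        X1, X2 = np.asarray(s1.features, float), np.asarray(s2.features, float)
        if X1.shape[1] != X2.shape[1]:
            raise ValueError("external embeddings differ in dimensionality")
        return EmbeddingPair(X1, X2, provenance="external")
    a, b = shared_features(s1, s2)
    G1t = lognorm_scale(a, target_sum, scale_clip)
    G2t = lognorm_scale(b, target_sum, scale_clip)
    if hvg:
        cols = _hvg_subset(G1t, G2t, int(hvg))
        G1t, G2t = G1t[:, cols], G2t[:, cols]
    return svd_embed(G1t, G2t, M)
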