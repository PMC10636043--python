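"""Probabilistic match calling from embeddings and matched coordinates.

For every slice-1 cell the K spatially closest slice-2 cells (in the
registered frame) form its candidate set; each candidate is scored by the
cosine similarity of the alignment embeddings, and its significance is the
exceedance probability of that similarity under an empirical null of
cosines between randomly sampled cross-slice cell pairs.  The add-one
estimator ``p = (#{null >= sim} + 1) / (n_null + 1)`` keeps p-values in
(0, 1]; candidates with ``p < threshold`` (default 0.05) are accepted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .graph import knn_indices
from .io import MatchTable

__all__ = [
    "NullDistribution",
    "build_null",
    "candidate_set",
    "candidate_sets",
    "empirical_pvalue",
    "call_matches",
    "similarity_score",
]


def _row_normalize(Z: np.ndarray) -> np.ndarray:
    Z = np.asarray(Z, dtype=float)
    nrm = np.linalg.norm(Z, axis=1, keepdims=True)
    return Z / np.maximum(nrm, 1e-300)


@dataclass
class NullDistribution:
    """Cosine similarities of randomly sampled cross-slice cell pairs."""

    samples: np.ndarray
    seed: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if np.any(np.abs(self.samples) > 1 + 1e-9):
            raise ValueError("null cosines must lie in [-1, 1]")
        self._sorted = np.sort(self.samples)

    @property
    def n(self) -> int:
        return self.samples.size


def build_null(Z1: np.ndarray, Z2: np.ndarray, n_null: int = 1000, seed: int = 0) -> NullDistribution:
    """Sample ``n_null`` uniform cross-slice pairs (with replacement)."""
    rng = np.random.default_rng(seed)
    i = rng.integers(0, Z1.shape[0], size=n_null)
    j = rng.integers(0, Z2.shape[0], size=n_null)
    U1, U2 = _row_normalize(Z1), _row_normalize(Z2)
    sims = np.einsum("ij,ij->i", U1[i], U2[j])
    return NullDistribution(np.clip(sims, -1, 1), seed=seed)


def candidate_sets(S1: np.ndarray, S2p: np.ndarray, K: int) -> np.ndarray:
    """K spatially nearest slice-2 cells per slice-1 cell, ties by index.

    ``S2p`` must already be in the registered (slice-1) frame.  ``K`` is
    capped at N2 with a warning-free shrink.
    """
    S2p = np.asarray(S2p, float)
    K = min(K, S2p.shape[0])
    return knn_indices(S2p, np.asarray(S1, float), K)


def candidate_set(i: int, S1: np.ndarray, S2p: np.ndarray, K: int) -> np.ndarray:
    """Candidate set of a single slice-1 cell."""
    return candidate_sets(np.asarray(S1, float)[[i]], S2p, K)[0]


def empirical_pvalue(sim, null: NullDistribution):
    """Add-one exceedance probability of ``sim`` under the null (scalar or array)."""
    sim = np.asarray(sim, dtype=float)
    n_ge = null.n - np.searchsorted(null._sorted, sim, side="left")
    p = (n_ge + 1) / (null.n + 1)
    return float(p) if p.ndim == 0 else p


def call_matches(
    Z1: np.ndarray,
    Z2: np.ndarray,
    S1: np.ndarray,
    S2p: np.ndarray,
    K: int = 50,
    threshold: float = 0.05,
    null: NullDistribution | None = None,
    n_null: int = 1000,
    seed: int = 0,
) -> MatchTable:
    """Score all candidates and flag those significant under the null.

    Returns a :class:`MatchTable` with one row per (cell, candidate) pair;
    the ``accepted`` flag marks ``pvalue < threshold``.  One null
    distribution (built here unless supplied) is shared by all cells.
    """
    if null is None:
        null = build_null(Z1, Z2, n_null=n_null, seed=seed)
    cand = candidate_sets(S1, S2p, K)
    n1, k = cand.shape
    U1, U2 = _row_normalize(Z1), _row_normalize(Z2)
    sims = np.einsum("ij,ikj->ik", U1, U2[cand])  # (n1, k)
    sims = np.clip(sims, -1, 1)
    pvals = empirical_pvalue(sims.ravel(), null)
    table = pd.DataFrame(
        {
            "source": np.repeat(np.arange(n1), k),
            "target": cand.ravel(),
            "cosine": sims.ravel(),
            "pvalue": pvals,
            "accepted": pvals < threshold,
        }
    )
    return MatchTable(table, threshold=threshold, k=k)


def similarity_score(m: MatchTable, n_cells: int | None = None) -> pd.Series:
    """Per slice-1 cell confidence: the maximum candidate cosine.

    Cells with no candidate rows get NaN (requires ``n_cells`` to know the
    full index range).
    """
    s = m.table.groupby("source")["cosine"].max()
    if n_cells is not None:
        s = s.reindex(np.arange(n_cells))
    s.name = "similarity_score"
    return s
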