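"""Per-slice spatial neighbourhood graphs and the normalised propagation operator.

Cells are nodes; edges connect spatial K-nearest neighbours (or all cells
within a radius).  Propagation uses the symmetric normalisation with
self-loops::

    A_hat = D~^{-1/2} (A + I) D~^{-1/2}

whose spectrum lies in [-1, 1], so repeated propagation never amplifies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

__all__ = [
    "SpatialGraph",
    "build_knn_graph",
    "build_radius_graph",
    "normalize_adjacency",
    "knn_indices",
    "write_edge_list",
]

_BRUTE_MAX = 2048  # below this, exact brute force with index tie-breaking


def knn_indices(ref: np.ndarray, query: np.ndarray, k: int, exclude_self: bool = False) -> np.ndarray:
    """Indices of the k nearest ``ref`` points for each ``query`` point.

    Euclidean distance; ties broken by lower index (exactly, via a stable
    argsort, for up to a few thousand points; KD-tree order beyond that).
    ``exclude_self`` removes the diagonal when ``query is ref``.
    """
    ref = np.asarray(ref, float)
    query = np.asarray(query, float)
    n = ref.shape[0]
    if k > n - int(exclude_self):
        raise ValueError(f"k={k} too large for {n} reference points")
    if n <= _BRUTE_MAX:
        d = cdist(query, ref)
        if exclude_self:
            np.fill_diagonal(d, np.inf)
        return np.argsort(d, axis=1, kind="stable")[:, :k]
    tree = cKDTree(ref)
    kk = k + 1 if exclude_self else k
    _, idx = tree.query(query, k=kk)
    idx = np.atleast_2d(idx)
    if exclude_self:
        rows = np.arange(query.shape[0])[:, None]
        mask = idx != rows
        # keep first k non-self neighbours per row
        out = np.empty((query.shape[0], k), dtype=int)
        for i in range(query.shape[0]):
            out[i] = idx[i][mask[i]][:k]
        return out
    return idx[:, :k]


@dataclass
class SpatialGraph:
    """Sparse symmetric binary adjacency with its normalised operator."""

    A: sp.csr_matrix
    mode: str = "knn"  # {"knn", "radius"}
    param: float = 0.0  # K for knn, r for radius
    _A_hat: sp.csr_matrix | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        A = sp.csr_matrix(self.A, dtype=float)
        if (A != A.T).nnz:
            raise ValueError("adjacency must be symmetric")
        if A.diagonal().any():
            raise ValueError("adjacency must have zero diagonal")
        A.data[:] = 1.0
        self.A = A

    @property
    def n(self) -> int:
        return self.A.shape[0]

    @property
    def A_hat(self) -> sp.csr_matrix:
        if self._A_hat is None:
            self._A_hat = normalize_adjacency(self.A)
        return self._A_hat

    def neighbors(self, i: int) -> np.ndarray:
        return self.A.indices[self.A.indptr[i] : self.A.indptr[i + 1]]


def build_knn_graph(coords: np.ndarray, K: int, mutual: bool = False) -> SpatialGraph:
    """Spatial K-nearest-neighbour graph, symmetrised by union.

    Directed K-NN edges by Euclidean distance (self excluded, distance ties
    by lower index) are symmetrised by union — an undirected edge exists if
    either endpoint selects the other.  ``mutual=True`` uses the
    intersection instead.
    """
    coords = np.asarray(coords, float)
    n = coords.shape[0]
    if K >= n:
        raise ValueError(f"K={K} must be < number of cells ({n})")
    nbr = knn_indices(coords, coords, K, exclude_self=True)
    rows = np.repeat(np.arange(n), K)
    D = sp.csr_matrix(
        (np.ones(n * K), (rows, nbr.ravel())), shape=(n, n)
    )
    if mutual:
        A = D.multiply(D.T)
    else:
        A = D + D.T
    A.data[:] = 1.0
    return SpatialGraph(sp.csr_matrix(A), mode="knn", param=float(K))


def build_radius_graph(coords: np.ndarray, r: float) -> SpatialGraph:
    """Graph with an edge iff 0 < distance <= r (symmetric by construction)."""
    if r <= 0:
        raise ValueError("radius must be positive")
    coords = np.asarray(coords, float)
    n = coords.shape[0]
    pairs = cKDTree(coords).query_pairs(r, output_type="ndarray")
    if pairs.size:
        d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
        pairs = pairs[d > 0]
    if pairs.size:
        i, j = pairs[:, 0], pairs[:, 1]
        A = sp.csr_matrix(
            (np.ones(2 * len(i)), (np.r_[i, j], np.r_[j, i])), shape=(n, n)
        )
        A.data[:] = 1.0
    else:
        A = sp.csr_matrix((n, n))
    deg = np.ravel(A.sum(axis=1))
    if np.any(deg == 0):
        warnings.warn(
            f"{int((deg == 0).sum())} isolated cells at radius {r}; "
            "self-loops keep propagation defined",
            stacklevel=2,
        )
    return SpatialGraph(A, mode="radius", param=float(r))


def normalize_adjacency(A: sp.spmatrix) -> sp.csr_matrix:
    """Symmetric normalisation with self-loops: D~^{-1/2} (A+I) D~^{-1/2}."""
    A = sp.csr_matrix(A, dtype=float)
    At = A + sp.identity(A.shape[0], format="csr")
    deg = np.ravel(At.sum(axis=1))
    dinv = 1.0 / np.sqrt(deg)
    Dinv = sp.diags(dinv)
    return sp.csr_matrix(Dinv @ At @ Dinv)


def write_edge_list(g: SpatialGraph, path: str) -> None:
    """Export undirected edges (i < j) as a two-column TSV."""
    coo = sp.triu(g.A, k=1).tocoo()
    order = np.lexsort((coo.col, coo.row))
    with open(path, "w") as fh:
        for i, j in zip(coo.row[order], coo.col[order]):
            fh.write(f"{i}\t{j}\n")
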