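"""Synthetic benchmark data: structured slices, noisy duplicates, splits.

The generator emulates the structure of the benchmark protocols on real
tissue: cell types arranged within spatial regions, negative-binomial
count noise, rigid rotation of the duplicate slice, and random splitting
into pseudo-slices.

A structured slice places cells in a rectangular grid of region blocks
(unequal region weights make the layout rotationally asymmetric, so rigid
registration has a unique optimum), draws each cell's type from its
region's composition, and samples counts from a negative binomial
parameterised by mean mu (the type's expression profile) and inverse
dispersion theta, via the Gamma-Poisson mixture:

    lambda ~ Gamma(shape=theta, scale=mu/theta),  x ~ Poisson(lambda)

giving E[x] = mu and Var[x] = mu + mu^2 / theta.  theta -> infinity
approaches Poisson noise; small theta is heavily overdispersed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp

from .graph import SpatialGraph
from .io import SpatialSlice

__all__ = [
    "SynthConfig",
    "sample_nb",
    "make_structured_slice",
    "duplicate_with_noise",
    "split_slice",
    "subsample",
    "corrupt_graph",
]

# default type-by-region composition: 4 regions sharing 3 cell types with
# different mixing proportions (types are spatially interlaced across regions)
_DEFAULT_COMPOSITION = (
    (0.70, 0.20, 0.10),
    (0.20, 0.70, 0.10),
    (0.10, 0.20, 0.70),
    (0.40, 0.40, 0.20),
)


@dataclass
class SynthConfig:
    """Parameters of the structured synthetic slice.

    ``grid`` tiles the rectangular ``domain`` into region blocks (row-major
    region ids); ``region_weights`` are the per-region cell fractions
    (unequal by default for asymmetry); ``composition[r][t]`` is the
    probability of type t in region r (rows sum to 1).  Type expression
    profiles are log-normal draws per gene; counts are NB with inverse
    dispersion ``nb_theta``.
    """

    n_cells: int = 500
    n_genes: int = 200
    grid: tuple[int, int] = (2, 2)
    n_types: int = 3
    domain: tuple[float, float] = (1.5, 1.0)
    region_weights: tuple[float, ...] = (0.35, 0.30, 0.20, 0.15)
    composition: tuple[tuple[float, ...], ...] = _DEFAULT_COMPOSITION
    expr_log_mean: float = 1.0
    expr_log_sd: float = 1.0
    nb_theta: float = 10.0
    rotate_deg: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nb_theta <= 0:
            raise ValueError("nb_theta must be positive")
        n_regions = self.grid[0] * self.grid[1]
        if len(self.region_weights) != n_regions:
            raise ValueError("region_weights length must equal grid cells")
        comp = np.asarray(self.composition, dtype=float)
        if comp.shape != (n_regions, self.n_types):
            raise ValueError("composition must be n_regions x n_types")
        if not np.allclose(comp.sum(axis=1), 1.0):
            raise ValueError("composition rows must sum to 1")

    @property
    def n_regions(self) -> int:
        return self.grid[0] * self.grid[1]


def sample_nb(mu: np.ndarray, theta: float, rng: np.random.Generator) -> np.ndarray:
    """Negative-binomial counts with mean ``mu``, inverse dispersion ``theta``.

    Sampled as a Gamma-Poisson mixture; ``mu = 0`` yields 0 almost surely.
    """
    mu = np.asarray(mu, dtype=float)
    lam = rng.gamma(shape=theta, scale=mu / theta)
    return rng.poisson(lam)


def make_structured_slice(cfg: SynthConfig | None = None) -> SpatialSlice:
    """Generate one labelled structured slice (bit-identical per seed)."""
    cfg = cfg or SynthConfig()
    rng = np.random.default_rng(cfg.seed)
    rows, cols = cfg.grid
    w, h = cfg.domain
    bw, bh = w / cols, h / rows
    region = rng.choice(cfg.n_regions, size=cfg.n_cells, p=np.asarray(cfg.region_weights))
    rr, rc = region // cols, region % cols
    coords = np.column_stack(
        [
            rc * bw + rng.uniform(0, bw, cfg.n_cells),
            rr * bh + rng.uniform(0, bh, cfg.n_cells),
        ]
    )
    comp = np.asarray(cfg.composition, dtype=float)
    cum = np.cumsum(comp, axis=1)
    u = rng.uniform(size=cfg.n_cells)
    cell_type = (u[:, None] > cum[region]).sum(axis=1)
    profiles = rng.lognormal(cfg.expr_log_mean, cfg.expr_log_sd, size=(cfg.n_types, cfg.n_genes))
    counts = sample_nb(profiles[cell_type], cfg.nb_theta, rng).astype(float)
    return SpatialSlice(
        features=counts,
        coords=coords,
        feature_names=[f"gene_{g}" for g in range(cfg.n_genes)],
        cell_type=np.array([f"T{t}" for t in cell_type], dtype=object),
        region=np.array([f"R{r}" for r in region], dtype=object),
    )


def duplicate_with_noise(
    s: SpatialSlice, theta: float, rotate_deg: float = 60.0, seed: int = 0
) -> SpatialSlice:
    """Duplicate a slice with NB resampling noise and a rigid rotation.

    Each count is replaced by an NB draw centred at the measured value
    (``mu`` = observed count, inverse dispersion ``theta``); coordinates are
    rotated by ``rotate_deg`` about the centroid; labels are copied.  The
    ground-truth pairing is the identity.
    """
    rng = np.random.default_rng(seed)
    counts = s.counts_dense()
    noisy = sample_nb(counts, theta, rng).astype(float)
    th = np.radians(rotate_deg)
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    mu = s.coords.mean(axis=0)
    coords = (s.coords - mu) @ R.T + mu
    return replace(s, features=noisy, coords=coords, feature_names=list(s.feature_names))


def split_slice(s: SpatialSlice, seed: int = 0) -> tuple[SpatialSlice, SpatialSlice]:
    """Random disjoint equal-size halves (without replacement)."""
    if s.n_cells < 2:
        raise ValueError("need at least 2 cells to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(s.n_cells)
    half = s.n_cells // 2
    return s.subset(np.sort(perm[:half])), s.subset(np.sort(perm[half:]))


def subsample(s: SpatialSlice, n: int, seed: int = 0) -> SpatialSlice:
    """Uniform subsample of n cells without replacement."""
    if n > s.n_cells:
        raise ValueError(f"cannot subsample {n} from {s.n_cells} cells")
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    return s.subset(np.sort(rng.choice(s.n_cells, size=n, replace=False)))


def corrupt_graph(g: SpatialGraph, mask_ratio: float, seed: int = 0) -> SpatialGraph:
    """Remove a uniform fraction of undirected edges (self-loops are added
    later by normalisation and are unaffected)."""
    if not 0 <= mask_ratio < 1:
        raise ValueError("mask_ratio must be in [0, 1)")
    rng = np.random.default_rng(seed)
    ut = sp.triu(g.A, k=1).tocoo()
    n_edges = ut.nnz
    n_drop = int(round(mask_ratio * n_edges))
    keep = np.ones(n_edges, dtype=bool)
    keep[rng.choice(n_edges, size=n_drop, replace=False)] = False
    i, j = ut.row[keep], ut.col[keep]
    A = sp.csr_matrix(
        (np.ones(2 * len(i)), (np.r_[i, j], np.r_[j, i])), shape=g.A.shape
    )
    return SpatialGraph(A, mode=g.mode, param=g.param)
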