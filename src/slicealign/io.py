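"""Data model and on-disk formats for spatial omics slices.

A *slice* is one spatially resolved omics measurement: a cells x features
count (or embedding) matrix, per-cell 2-D coordinates, and optional
categorical annotation (cell type, spatial region).  Two storage layouts
are supported:

* AnnData ``.h5ad`` — ``X`` holds the feature matrix, ``obsm[coord_key]``
  the N x 2 coordinate array, and ``obs`` columns the labels.
* a plain-text directory — ``features.mtx`` (MatrixMarket) or
  ``features.csv`` (header = feature names), ``coords.csv`` with columns
  ``x,y``, and an optional ``labels.csv`` with ``cell_type``/``region``
  columns.

Cell indices are 0-based internally and in every output file.
Unannotated cells carry the sentinel label ``"NA"``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

NA_LABEL = "NA"

__all__ = [
    "SpatialSlice",
    "MatchTable",
    "ConfigurationError",
    "FormatError",
    "read_slice",
    "write_slice",
    "write_matches",
    "read_matches",
    "NA_LABEL",
]


class ConfigurationError(ValueError):
    """A requested key/parameter does not match the file or config."""


class FormatError(ValueError):
    """The file content violates a structural invariant."""


def _as_label_array(values, n: int) -> np.ndarray:
    arr = np.asarray(values, dtype=object)
    if arr.shape != (n,):
        raise FormatError(f"label column has length {arr.shape}, expected {n}")
    out = np.array([NA_LABEL if (v is None or (isinstance(v, float) and np.isnan(v))) else str(v) for v in arr], dtype=object)
    return out


@dataclass
class SpatialSlice:
    """One spatial omics dataset: features + 2-D coordinates + labels.

    Parameters
    ----------
    features
        ``(N, G)`` matrix of raw counts, or of precomputed low-dimensional
        embeddings when ``is_embedding`` is true.  Sparse input stays sparse.
    coords
        ``(N, 2)`` planar positions, one physical length unit per slice
        (treated as dimensionless; no unit conversion is ever applied).
    feature_names
        ``G`` unique names.
    cell_type, region
        Optional per-cell categorical labels (strings; ``"NA"`` = missing).
    is_embedding
        True when ``features`` is a precomputed embedding (e.g. a
        cross-modality integration output) rather than counts.
    """

    features: np.ndarray | sp.spmatrix
    coords: np.ndarray
    feature_names: list[str] = field(default_factory=list)
    cell_type: np.ndarray | None = None
    region: np.ndarray | None = None
    is_embedding: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise FormatError(f"coords must be N x 2, got {self.coords.shape}")
        n = self.features.shape[0]
        if self.coords.shape[0] != n:
            raise FormatError(
                f"coords rows ({self.coords.shape[0]}) != feature rows ({n})"
            )
        if not np.isfinite(self.coords).all():
            raise FormatError("coords contain NaN/inf")
        if not self.feature_names:
            self.feature_names = [f"feat_{i}" for i in range(self.features.shape[1])]
        self.feature_names = [str(x) for x in self.feature_names]
        if len(self.feature_names) != self.features.shape[1]:
            raise FormatError("feature_names length != feature columns")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise FormatError("feature_names are not unique")
        for attr in ("cell_type", "region"):
            v = getattr(self, attr)
            if v is not None:
                setattr(self, attr, _as_label_array(v, n))

    @property
    def n_cells(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def counts_dense(self) -> np.ndarray:
        x = self.features
        return np.asarray(x.todense()) if sp.issparse(x) else np.asarray(x)

    def subset(self, idx: np.ndarray) -> "SpatialSlice":
        """Return a new slice restricted to the given cell indices."""
        idx = np.asarray(idx)
        return replace(
            self,
            features=self.features[idx],
            coords=self.coords[idx],
            cell_type=None if self.cell_type is None else self.cell_type[idx],
            region=None if self.region is None else self.region[idx],
            feature_names=list(self.feature_names),
        )

    def select_features(self, names: list[str]) -> "SpatialSlice":
        pos = {n: i for i, n in enumerate(self.feature_names)}
        cols = np.array([pos[n] for n in names], dtype=int)
        return replace(
            self,
            features=self.features[:, cols],
            coords=self.coords,
            feature_names=list(names),
        )

    def filter_cells(self, min_counts: int = 1) -> "SpatialSlice":
        """Drop cells whose total count is below ``min_counts`` (counts only)."""
        if self.is_embedding:
            return self
        totals = np.ravel(self.features.sum(axis=1))
        return self.subset(np.flatnonzero(totals >= min_counts))

    def drop_unannotated(self) -> "SpatialSlice":
        """Drop cells whose cell type or region label is the NA sentinel."""
        keep = np.ones(self.n_cells, dtype=bool)
        for lab in (self.cell_type, self.region):
            if lab is not None:
                keep &= lab != NA_LABEL
        return self.subset(np.flatnonzero(keep))


@dataclass
class MatchTable:
    """Per-cell candidate matches between two slices.

    ``table`` columns: ``source`` (index into slice 1), ``target`` (index
    into slice 2), ``cosine`` in [-1, 1], ``pvalue`` in (0, 1], ``accepted``
    (bool, equivalent to ``pvalue < threshold``).  At most K rows per
    source, targets drawn from that source's spatial candidate set.
    """

    table: pd.DataFrame
    threshold: float = 0.05
    k: int | None = None

    def __post_init__(self) -> None:
        cols = ["source", "target", "cosine", "pvalue", "accepted"]
        missing = set(cols) - set(self.table.columns)
        if missing:
            raise FormatError(f"match table missing columns {sorted(missing)}")
        t = self.table[cols].copy()
        t["source"] = t["source"].astype(int)
        t["target"] = t["target"].astype(int)
        expect = t["pvalue"].to_numpy() < self.threshold
        if not np.array_equal(t["accepted"].to_numpy(dtype=bool), expect):
            raise FormatError("accepted flag inconsistent with pvalue < threshold")
        t = t.sort_values(
            ["source", "pvalue", "target"], kind="stable", ignore_index=True
        )
        self.table = t

    def __len__(self) -> int:
        return len(self.table)

    @property
    def accepted(self) -> pd.DataFrame:
        return self.table[self.table["accepted"]]

    def best_matches(self) -> pd.DataFrame:
        """One row per source: minimal p-value, ties by max cosine then index."""
        t = self.table.sort_values(
            ["source", "pvalue", "cosine", "target"],
            ascending=[True, True, False, True],
            kind="stable",
        )
        return t.groupby("source", as_index=False).first()


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_slice(
    path: str,
    coord_key: str = "spatial",
    type_key: str = "cell_type",
    region_key: str = "region",
    is_embedding: bool = False,
) -> SpatialSlice:
    """Read a slice from an ``.h5ad`` file or a CSV/MTX directory."""
    if str(path).endswith(".h5ad"):
        return _read_h5ad(path, coord_key, type_key, region_key, is_embedding)
    return _read_dir(path, type_key, region_key, is_embedding)


def _read_h5ad(path, coord_key, type_key, region_key, is_embedding):
    adata = ad.read_h5ad(path)
    if coord_key not in adata.obsm:
        raise ConfigurationError(
            f"coordinate key {coord_key!r} not found in obsm of {path}"
        )
    coords = np.asarray(adata.obsm[coord_key])
    labels = {}
    for attr, key in (("cell_type", type_key), ("region", region_key)):
        labels[attr] = (
            adata.obs[key].astype(str).to_numpy() if key in adata.obs else None
        )
    flag = bool(adata.uns.get("is_embedding", is_embedding))
    return SpatialSlice(
        features=adata.X.copy() if sp.issparse(adata.X) else np.asarray(adata.X),
        coords=coords,
        feature_names=list(adata.var_names),
        cell_type=labels["cell_type"],
        region=labels["region"],
        is_embedding=flag,
    )


def _read_dir(path, type_key, region_key, is_embedding):
    mtx = os.path.join(path, "features.mtx")
    csv = os.path.join(path, "features.csv")
    if os.path.exists(mtx):
        features = sp.csr_matrix(scipy.io.mmread(mtx))
        names_file = os.path.join(path, "features.txt")
        names = (
            [l.strip() for l in open(names_file)] if os.path.exists(names_file) else []
        )
    elif os.path.exists(csv):
        df = pd.read_csv(csv)
        features = df.to_numpy(dtype=float)
        names = list(df.columns)
    else:
        raise ConfigurationError(f"no features.mtx/features.csv under {path}")
    cdf = pd.read_csv(os.path.join(path, "coords.csv"))
    for col in ("x", "y"):
        if col not in cdf.columns:
            raise ConfigurationError("coords.csv must have columns x,y")
    coords = cdf[["x", "y"]].to_numpy(dtype=float)
    cell_type = region = None
    labels_csv = os.path.join(path, "labels.csv")
    if os.path.exists(labels_csv):
        ldf = pd.read_csv(labels_csv)
        if type_key in ldf.columns:
            cell_type = ldf[type_key].astype(str).to_numpy()
        if region_key in ldf.columns:
            region = ldf[region_key].astype(str).to_numpy()
    return SpatialSlice(features, coords, names, cell_type, region, is_embedding)


def write_slice(s: SpatialSlice, path: str, coord_key: str = "spatial") -> None:
    """Write a slice as ``.h5ad`` (path ends in .h5ad) or a CSV/MTX directory."""
    if str(path).endswith(".h5ad"):
        obs = pd.DataFrame(index=[str(i) for i in range(s.n_cells)])
        if s.cell_type is not None:
            obs["cell_type"] = s.cell_type.astype(str)
        if s.region is not None:
            obs["region"] = s.region.astype(str)
        adata = ad.AnnData(
            X=s.features.copy() if sp.issparse(s.features) else np.asarray(s.features),
            obs=obs,
            var=pd.DataFrame(index=s.feature_names),
        )
        adata.obsm[coord_key] = s.coords
        adata.uns["is_embedding"] = bool(s.is_embedding)
        adata.write_h5ad(path)
        return
    os.makedirs(path, exist_ok=True)
    if sp.issparse(s.features):
        scipy.io.mmwrite(os.path.join(path, "features.mtx"), s.features)
        with open(os.path.join(path, "features.txt"), "w") as fh:
            fh.write("\n".join(s.feature_names) + "\n")
    else:
        pd.DataFrame(np.asarray(s.features), columns=s.feature_names).to_csv(
            os.path.join(path, "features.csv"), index=False
        )
    pd.DataFrame(s.coords, columns=["x", "y"]).to_csv(
        os.path.join(path, "coords.csv"), index=False
    )
    if s.cell_type is not None or s.region is not None:
        ldf = pd.DataFrame(index=range(s.n_cells))
        if s.cell_type is not None:
            ldf["cell_type"] = s.cell_type
        if s.region is not None:
            ldf["region"] = s.region
        ldf.to_csv(os.path.join(path, "labels.csv"), index=False)


_MATCH_HEADER = ["source", "target", "cosine", "pvalue", "accepted"]


def write_matches(m: MatchTable, path: str) -> None:
    """Write a match table as TSV, bit-stably ordered by (source, pvalue)."""
    t = m.table.copy()
    t["accepted"] = t["accepted"].astype(int)
    t.to_csv(path, sep="\t", index=False, float_format="%.10g", columns=_MATCH_HEADER)


def read_matches(path: str, threshold: float = 0.05) -> MatchTable:
    t = pd.read_csv(path, sep="\t")
    t["accepted"] = t["accepted"].astype(bool)
    return MatchTable(t, threshold=threshold)
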