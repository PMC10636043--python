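"""End-to-end orchestration: config, seeding, alignment runs, benchmarks.

The pipeline runs model -> represent -> align: shared SVD embedding,
per-slice spatial graphs, LGCN holistic features, adversarial training,
coordinate registration, probabilistic match calling, and (when labels or
ground truth are available) evaluation metrics.

Configuration is a nested dict validated against :data:`DEFAULT_CONFIG`
(unknown keys are rejected).  A single global seed fans out
deterministically to per-stage seeds: ``SeedSequence(seed)`` generates one
32-bit word per named stage in the fixed order ``synth, model, null, icp,
bench`` (each reduced mod 2**31).
"""

from __future__ import annotations

import copy
import json
import logging
import os
import time

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .adversarial import AlignConfig, train
from .coords import AffineTransform, icp_register, manual_transform
from .graph import SpatialGraph, build_knn_graph, build_radius_graph
from .io import ConfigurationError, MatchTable, SpatialSlice, read_slice, write_matches
from .lgcn import holistic_pair
from .matchcall import call_matches
from .metrics import (
    edge_score,
    f1_scores,
    ground_truth_accuracy,
    label_accuracy,
    procrustes_rotation,
    rotation_error_deg,
)
from .preprocess import embed_pair
from .synth import SynthConfig, corrupt_graph, duplicate_with_noise, make_structured_slice, split_slice, subsample

logger = logging.getLogger("slicealign")

__all__ = ["DEFAULT_CONFIG", "load_config", "derive_seeds", "align_pair", "run_align", "run_benchmark", "AlignmentResult"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "min_counts": 1,
    "log_level": "INFO",
    "preprocess": {"svd_dim": 30, "target_sum": 1e4, "scale_clip": 10.0, "hvg": 0},
    "graph": {"mode": "knn", "K": 50, "K1": None, "K2": None, "radius": None, "mutual": False},
    "lgcn": {"L": 3},
    "model": {
        "alpha": 0.5,
        "clip_ratio": 0.6,
        "lr": 1e-4,
        "steps": 500,
        "embed_dim": 50,
        "hidden": 256,
        "embed_hidden": 2048,
        "weight_clip": 0.1,
        "ablate": "none",
    },
    "coords": {
        "method": "icp",  # {"icp", "manual", "external", "none"}
        "max_iter": 50,
        "tol": 1e-6,
        "n_starts": 12,
        "rotate": 0.0,
        "scale": 1.0,
        "translate": (0.0, 0.0),
        "matrix_file": None,
    },
    "match": {"K": None, "threshold": 0.05, "n_null": 1000},
    # reduced problem sizes used by the repeated benchmark protocols
    "benchmark": {
        "n_cells": 300,
        "n_genes": 150,
        "repeats": 8,
        "theta_grid": (1e6, 10.0, 1.0),
        "mask_ratios": (0.1, 0.3, 0.5, 0.7, 0.9),
        "sizes": (200, 400),
        "rotate_deg": 60.0,
        "nb_theta": 10.0,
        "svd_dim": 20,
        "K": 20,
        "steps": 120,
        "embed_dim": 30,
        "hidden": 128,
        "embed_hidden": 512,
        "match_K": 20,
    },
}


def _merge(defaults: dict, user: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, val in user.items():
        if key not in defaults:
            raise ConfigurationError(f"unknown config key {path + key!r}")
        if isinstance(defaults[key], dict):
            if not isinstance(val, dict):
                raise ConfigurationError(f"{path + key!r} must be a mapping")
            out[key] = _merge(defaults[key], val, path + key + ".")
        else:
            out[key] = val
    return out


def load_config(src: str | dict | None = None) -> dict:
    """Validate a config (YAML path or dict) against the schema defaults."""
    if src is None:
        user = {}
    elif isinstance(src, dict):
        user = src
    else:
        with open(src) as fh:
            user = yaml.safe_load(fh) or {}
    cfg = _merge(DEFAULT_CONFIG, user)
    logging.basicConfig(level=getattr(logging, str(cfg["log_level"]).upper(), logging.INFO))
    return cfg


_SEED_STAGES = ("synth", "model", "null", "icp", "bench")


def derive_seeds(seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds from the global seed."""
    state = np.random.SeedSequence(seed).generate_state(len(_SEED_STAGES))
    return {name: int(s % 2**31) for name, s in zip(_SEED_STAGES, state)}


def _build_graph(coords: np.ndarray, gcfg: dict, which: int) -> SpatialGraph:
    if gcfg["mode"] == "radius":
        return build_radius_graph(coords, gcfg["radius"])
    K = gcfg[f"K{which}"] if gcfg.get(f"K{which}") else gcfg["K"]
    K = min(int(K), coords.shape[0] - 1)
    return build_knn_graph(coords, K, mutual=gcfg["mutual"])


class AlignmentResult:
    """Artifacts of one alignment run."""

    def __init__(self, model, Z1, Z2, transform, matches, g1, g2, state=None):
        self.model = model
        self.Z1, self.Z2 = Z1, Z2
        self.transform: AffineTransform = transform
        self.matches: MatchTable = matches
        self.g1, self.g2 = g1, g2

    def best(self) -> pd.DataFrame:
        return self.matches.best_matches()


def align_pair(
    s1: SpatialSlice,
    s2: SpatialSlice,
    cfg: dict | None = None,
    graph_hook=None,
) -> AlignmentResult:
    """Run the full alignment of two in-memory slices.

    ``graph_hook(g1, g2) -> (g1, g2)`` lets benchmark protocols corrupt the
    spatial graphs before propagation.
    """
    cfg = load_config(cfg) if not (isinstance(cfg, dict) and "model" in cfg) else cfg
    seeds = derive_seeds(cfg["seed"])
    pp, mc = cfg["preprocess"], cfg["model"]
    if not s1.is_embedding:
        s1 = s1.filter_cells(cfg["min_counts"])
    if not s2.is_embedding:
        s2 = s2.filter_cells(cfg["min_counts"])
    ep = embed_pair(
        s1, s2, M=pp["svd_dim"], target_sum=pp["target_sum"],
        scale_clip=pp["scale_clip"], hvg=pp["hvg"],
    )
    g1 = _build_graph(s1.coords, cfg["graph"], 1)
    g2 = _build_graph(s2.coords, cfg["graph"], 2)
    if graph_hook is not None:
        g1, g2 = graph_hook(g1, g2)
    L = 0 if mc["ablate"] == "no_lgcn" else int(cfg["lgcn"]["L"])
    h1, h2 = holistic_pair(ep, g1, g2, L=L)
    acfg = AlignConfig(
        alpha=mc["alpha"], clip_ratio=mc["clip_ratio"], lr=mc["lr"],
        steps=mc["steps"], seed=seeds["model"], embed_dim=mc["embed_dim"],
        hidden=mc["hidden"], embed_hidden=mc["embed_hidden"],
        weight_clip=mc["weight_clip"], ablate=mc["ablate"],
    )
    model = train(h1, h2, acfg)
    Z1, Z2 = model.project(h1.Xt), model.project(h2.Xt)

    ccfg = cfg["coords"]
    if ccfg["method"] == "icp":
        transform = icp_register(
            s1.coords, s2.coords, max_iter=ccfg["max_iter"], tol=ccfg["tol"],
            n_starts=ccfg["n_starts"], seed=seeds["icp"],
        )
    elif ccfg["method"] == "manual":
        transform = manual_transform(
            ccfg["rotate"], ccfg["scale"], tuple(ccfg["translate"]),
            center=tuple(s2.coords.mean(axis=0)),
        )
    elif ccfg["method"] == "external":
        transform = AffineTransform(np.loadtxt(ccfg["matrix_file"]), source="external")
    else:
        transform = AffineTransform(np.eye(3), source="manual")
    S2p = transform.apply(s2.coords)

    m = cfg["match"]
    K = int(m["K"]) if m["K"] else int(cfg["graph"]["K"])  # defaults to graph K
    K = min(K, s2.n_cells)
    matches = call_matches(
        Z1, Z2, s1.coords, S2p, K=K, threshold=m["threshold"],
        n_null=m["n_null"], seed=seeds["null"],
    )
    return AlignmentResult(model, Z1, Z2, transform, matches, g1, g2)


def evaluate_alignment(
    res: AlignmentResult,
    s1: SpatialSlice,
    s2: SpatialSlice,
    truth: np.ndarray | None = None,
    applied_rotation: float | None = None,
) -> dict:
    """Metrics of an alignment run (those whose inputs are available)."""
    best = res.best()
    src = best["source"].to_numpy()
    tgt = best["target"].to_numpy()
    out: dict = {
        "n_matched_cells": int(len(best)),
        "n_accepted_pairs": int(res.matches.table["accepted"].sum()),
        "mean_best_cosine": float(best["cosine"].mean()),
    }
    if truth is not None:
        full = np.full(s1.n_cells, -1, dtype=int)
        full[src] = tgt
        out["ground_truth_accuracy"] = ground_truth_accuracy(full, truth)
    if len(best) >= 2:
        angle, resid, refl = procrustes_rotation(s1.coords[src], s2.coords[tgt])
        out["procrustes_rotation_deg"] = angle
        out["procrustes_residual"] = resid
        out["procrustes_reflection"] = refl
        if applied_rotation is not None:
            # corrective angle undoes the applied rotation
            out["rotation_error_deg"] = rotation_error_deg(angle, -applied_rotation)
    out["edge_score"] = edge_score(src, tgt, res.g1, res.g2)
    if s1.cell_type is not None and s2.cell_type is not None:
        rep = label_accuracy(src, tgt, s1.cell_type, s2.cell_type, s1.region, s2.region)
        out["type_accuracy"] = rep.type_accuracy
        if s1.region is not None and s2.region is not None:
            out["region_accuracy"] = rep.region_accuracy
            out["joint_accuracy"] = rep.joint_accuracy
        out.update(
            f1_scores(src, tgt, s1.cell_type, s2.cell_type, s1.region, s2.region)
        )
    return out


def run_align(cfg: dict | str | None, slice1, slice2, outdir: str) -> dict:
    """Align two slices (paths or SpatialSlice) and write artifacts.

    Writes embeddings, the 3x3 transform, the match TSV, metrics JSON and a
    provenance record into ``outdir``; returns the metrics dict.
    """
    cfg = load_config(cfg) if not (isinstance(cfg, dict) and "model" in cfg) else cfg
    os.makedirs(outdir, exist_ok=True)
    s1 = read_slice(slice1) if isinstance(slice1, (str, os.PathLike)) else slice1
    s2 = read_slice(slice2) if isinstance(slice2, (str, os.PathLike)) else slice2
    t0 = time.time()
    res = align_pair(s1, s2, cfg)
    metrics = evaluate_alignment(res, s1, s2)
    metrics["runtime_s"] = round(time.time() - t0, 3)
    np.savetxt(os.path.join(outdir, "transform.txt"), res.transform.matrix, fmt="%.12g")
    np.savetxt(os.path.join(outdir, "Z1.csv"), res.Z1, delimiter=",", fmt="%.8g")
    np.savetxt(os.path.join(outdir, "Z2.csv"), res.Z2, delimiter=",", fmt="%.8g")
    write_matches(res.matches, os.path.join(outdir, "matches.tsv"))
    with open(os.path.join(outdir, "metrics.json"), "w") as fh:
        json.dump(metrics, fh, indent=2, default=float)
    prov = {
        "slicealign_version": __version__,
        "numpy_version": np.__version__,
        "config": _jsonable(cfg),
    }
    with open(os.path.join(outdir, "provenance.json"), "w") as fh:
        json.dump(prov, fh, indent=2)
    logger.info("alignment written to %s", outdir)
    return metrics


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# benchmark protocols
# ---------------------------------------------------------------------------

def _bench_align_cfg(cfg: dict, seed: int, coords_method: str, ablate: str = "none") -> dict:
    """Reduced-scale alignment config used inside benchmark loops."""
    b = cfg["benchmark"]
    sub = copy.deepcopy(cfg)
    sub["seed"] = seed
    sub["preprocess"]["svd_dim"] = b["svd_dim"]
    sub["graph"]["K"] = b["K"]
    sub["model"].update(
        steps=b["steps"], embed_dim=b["embed_dim"], hidden=b["hidden"],
        embed_hidden=b["embed_hidden"], ablate=ablate,
    )
    sub["coords"]["method"] = coords_method
    sub["match"]["K"] = b["match_K"]
    return sub


def _bench_slice(cfg: dict, seed: int) -> SpatialSlice:
    b = cfg["benchmark"]
    return make_structured_slice(
        SynthConfig(n_cells=b["n_cells"], n_genes=b["n_genes"], nb_theta=b["nb_theta"], seed=seed)
    )


def run_benchmark(cfg: dict | str | None, task: str, ablate: str = "none") -> pd.DataFrame:
    """Run a named benchmark protocol on synthetic slices.

    Tasks: ``duplicate`` (NB-noise grid x repeats, rotated copies),
    ``split`` (random equal halves), ``corruption`` (edge-mask sweep) and
    ``scaling`` (subsampled sizes).  Returns one tidy row per run.
    """
    cfg = load_config(cfg) if not (isinstance(cfg, dict) and "model" in cfg) else cfg
    b = cfg["benchmark"]
    seeds = derive_seeds(cfg["seed"])
    rep_seeds = [int(s % 2**31) for s in np.random.SeedSequence(seeds["bench"]).generate_state(b["repeats"])]
    rows = []
    base = _bench_slice(cfg, seeds["synth"])
    if task == "duplicate":
        for theta in b["theta_grid"]:
            for r, rs in enumerate(rep_seeds):
                dup = duplicate_with_noise(base, theta, b["rotate_deg"], seed=rs)
                sub = _bench_align_cfg(cfg, rs, "icp", ablate)
                res = align_pair(base, dup, sub)
                m = evaluate_alignment(res, base, dup, truth=np.arange(base.n_cells),
                                       applied_rotation=b["rotate_deg"])
                rows.append({"task": task, "theta": theta, "repeat": r, **m})
    elif task == "split":
        for r, rs in enumerate(rep_seeds):
            a, bb = split_slice(base, seed=rs)
            sub = _bench_align_cfg(cfg, rs, "none", ablate)
            res = align_pair(a, bb, sub)
            m = evaluate_alignment(res, a, bb)
            rows.append({"task": task, "repeat": r, **m})
    elif task == "corruption":
        theta = b["nb_theta"]
        for ratio in b["mask_ratios"]:
            for r, rs in enumerate(rep_seeds):
                dup = duplicate_with_noise(base, theta, b["rotate_deg"], seed=rs)
                sub = _bench_align_cfg(cfg, rs, "icp", ablate)
                hook = lambda g1, g2, _rs=rs, _ratio=ratio: (
                    corrupt_graph(g1, _ratio, seed=_rs),
                    corrupt_graph(g2, _ratio, seed=_rs + 1),
                )
                res = align_pair(base, dup, sub, graph_hook=hook)
                m = evaluate_alignment(res, base, dup, truth=np.arange(base.n_cells),
                                       applied_rotation=b["rotate_deg"])
                rows.append({"task": task, "mask_ratio": ratio, "repeat": r, **m})
    elif task == "scaling":
        for n in b["sizes"]:
            for r, rs in enumerate(rep_seeds):
                ss = subsample(base, min(n, base.n_cells), seed=rs)
                dup = duplicate_with_noise(ss, b["nb_theta"], b["rotate_deg"], seed=rs)
                sub = _bench_align_cfg(cfg, rs, "icp", ablate)
                t0 = time.time()
                res = align_pair(ss, dup, sub)
                m = evaluate_alignment(res, ss, dup, truth=np.arange(ss.n_cells),
                                       applied_rotation=b["rotate_deg"])
                m["runtime_s"] = round(time.time() - t0, 3)
                rows.append({"task": task, "n_cells": ss.n_cells, "repeat": r, **m})
    else:
        raise ConfigurationError(f"unknown benchmark task {task!r}")
    return pd.DataFrame(rows)
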