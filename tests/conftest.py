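import numpy as np
import pytest

from slicealign import SynthConfig, make_structured_slice


@pytest.fixture()
def unit_square():
    return np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])


@pytest.fixture()
def tiny_slice():
    """20-cell labelled synthetic slice for cheap integration checks."""
    return make_structured_slice(SynthConfig(n_cells=20, n_genes=15, seed=3))


@pytest.fixture()
def small_slice():
    """120-cell slice, enough structure for end-to-end runs."""
    return make_structured_slice(SynthConfig(n_cells=120, n_genes=60, seed=5))


@pytest.fixture()
def fast_cfg():
    """Reduced-scale pipeline config for quick end-to-end tests."""
    from slicealign.pipeline import load_config

    return load_config(
        {
            "seed": 11,
            "preprocess": {"svd_dim": 10},
            "graph": {"K": 8},
            "model": {
                "steps": 40,
                "embed_dim": 16,
                "hidden": 32,
                "embed_hidden": 64,
            },
            "match": {"K": 8},
            "benchmark": {
                "n_cells": 120,
                "n_genes": 60,
                "repeats": 2,
                "svd_dim": 10,
                "K": 8,
                "steps": 40,
                "embed_dim": 16,
                "hidden": 32,
                "embed_hidden": 64,
                "match_K": 8,
            },
        }
    )
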