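import numpy as np
import pytest

from slicealign import (
    SynthConfig,
    build_knn_graph,
    corrupt_graph,
    duplicate_with_noise,
    make_structured_slice,
    sample_nb,
    split_slice,
    subsample,
)


def test_single_region_single_type_constant_labels():
    cfg = SynthConfig(
        n_cells=30, n_genes=10, grid=(1, 1), n_types=1,
        region_weights=(1.0,), composition=((1.0,),), seed=0,
    )
    s = make_structured_slice(cfg)
    assert set(s.cell_type) == {"T0"} and set(s.region) == {"R0"}


def test_structured_slice_reproducible_and_labeled():
    a = make_structured_slice(SynthConfig(n_cells=50, seed=4))
    b = make_structured_slice(SynthConfig(n_cells=50, seed=4))
    np.testing.assert_array_equal(a.counts_dense(), b.counts_dense())
    np.testing.assert_array_equal(a.coords, b.coords)
    assert set(a.region) <= {"R0", "R1", "R2", "R3"}
    # region labels match the spatial block the cell sits in
    w, h = 1.5, 1.0
    for c, r in zip(a.coords, a.region):
        col, row = int(c[0] // (w / 2)), int(c[1] // (h / 2))
        assert r == f"R{row * 2 + col}"


def test_high_theta_limit_is_poisson_like():
    cfg = SynthConfig(n_cells=2000, n_genes=50, nb_theta=1e6, seed=1)
    s = make_structured_slice(cfg)
    # restrict to one type so each gene has a single NB mean
    mask = s.cell_type == "T0"
    x = s.counts_dense()[mask]
    mean, var = x.mean(0), x.var(0)
    big = mean > 5
    assert np.median(np.abs(var[big] / mean[big] - 1)) < 0.05


def test_sample_nb_zero_mean_and_config_validation():
    rng = np.random.default_rng(0)
    assert np.all(sample_nb(np.zeros(100), 5.0, rng) == 0)
    with pytest.raises(ValueError):
        SynthConfig(nb_theta=0.0)
    with pytest.raises(ValueError):
        SynthConfig(region_weights=(1.0,))


def test_duplicate_preserves_mean_at_low_noise():
    s = make_structured_slice(SynthConfig(n_cells=200, n_genes=80, seed=2))
    dup = duplicate_with_noise(s, theta=1e6, rotate_deg=0.0, seed=3)
    np.testing.assert_allclose(dup.coords, s.coords, atol=1e-12)
    x, y = s.counts_dense(), dup.counts_dense()
    # per-gene empirical mean within 3 SE of the original
    diff = y.mean(0) - x.mean(0)
    se = np.sqrt(np.maximum(y.var(0), 1e-12) / y.shape[0])
    assert np.mean(np.abs(diff) <= 3 * np.maximum(se, 1e-6)) > 0.95
    # zero counts stay zero almost surely
    assert np.all(y[x == 0] == 0)


def test_duplicate_variance_matches_nb_moments():
    rng_mu = 10.0
    s_counts = np.full((10000, 1), rng_mu)
    from slicealign.io import SpatialSlice

    s = SpatialSlice(s_counts, np.zeros((10000, 2)))
    dup = duplicate_with_noise(s, theta=1.0, rotate_deg=0.0, seed=5)
    v = dup.counts_dense().var()
    expected = rng_mu + rng_mu**2 / 1.0  # 110
    assert v == pytest.approx(expected, rel=0.1)


def test_duplicate_rotates_about_centroid():
    s = make_structured_slice(SynthConfig(n_cells=40, seed=6))
    dup = duplicate_with_noise(s, theta=10.0, rotate_deg=60.0, seed=7)
    np.testing.assert_allclose(dup.coords.mean(0), s.coords.mean(0), atol=1e-9)
    d0 = np.linalg.norm(s.coords - s.coords.mean(0), axis=1)
    d1 = np.linalg.norm(dup.coords - dup.coords.mean(0), axis=1)
    np.testing.assert_allclose(d0, d1, atol=1e-9)


def test_split_slice_disjoint_halves():
    s = make_structured_slice(SynthConfig(n_cells=4, seed=8))
    a, b = split_slice(s, seed=1)
    assert a.n_cells == b.n_cells == 2
    a2, b2 = split_slice(s, seed=1)
    np.testing.assert_array_equal(a.coords, a2.coords)
    # odd N: sizes differ by one
    s5 = make_structured_slice(SynthConfig(n_cells=5, seed=8))
    a, b = split_slice(s5, seed=1)
    assert {a.n_cells, b.n_cells} == {2, 3}


def test_split_label_proportions_roughly_preserved():
    s = make_structured_slice(SynthConfig(n_cells=400, seed=9))
    a, b = split_slice(s, seed=2)
    for t in set(s.cell_type):
        p_full = np.mean(s.cell_type == t)
        p_half = np.mean(a.cell_type == t)
        # hypergeometric SE for sampling half without replacement
        se = np.sqrt(p_full * (1 - p_full) / a.n_cells * 0.5)
        assert abs(p_half - p_full) < 4 * se + 0.02


def test_subsample_bounds_and_identity():
    s = make_structured_slice(SynthConfig(n_cells=30, seed=10))
    assert subsample(s, 30, seed=0).n_cells == 30
    assert subsample(s, 10, seed=0).n_cells == 10
    with pytest.raises(ValueError):
        subsample(s, 31, seed=0)
    with pytest.raises(ValueError):
        subsample(s, 0, seed=0)


def test_corrupt_graph_edge_counts():
    rng = np.random.default_rng(11)
    g = build_knn_graph(rng.uniform(size=(30, 2)), 3)
    n_edges = g.A.nnz // 2
    same = corrupt_graph(g, 0.0, seed=0)
    assert same.A.nnz == g.A.nnz
    half = corrupt_graph(g, 0.5, seed=0)
    assert half.A.nnz // 2 == n_edges - round(0.5 * n_edges)
    # heavily masked graphs may isolate nodes; normalisation still works
    heavy = corrupt_graph(g, 0.9, seed=0)
    assert np.isfinite(heavy.A_hat.toarray()).all()
    with pytest.raises(ValueError):
        corrupt_graph(g, 1.0, seed=0)


def test_nb_sampler_moments_on_grid():
    rng = np.random.default_rng(12)
    n = 60000
    for mu in (0.5, 4.0):
        for theta in (0.5, 10.0):
            x = sample_nb(np.full(n, mu), theta, rng)
            v = mu + mu**2 / theta
            se_mean = np.sqrt(v / n)
            assert abs(x.mean() - mu) < 4 * se_mean
            m4 = np.mean((x - x.mean()) ** 4)
            se_var = np.sqrt(max(m4 - x.var() ** 2, 0) / n)
            assert abs(x.var() - v) < 5 * se_var
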