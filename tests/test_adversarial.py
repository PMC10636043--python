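import numpy as np
import pytest

from slicealign import (
    AlignConfig,
    build_knn_graph,
    dynamic_clip,
    holistic_pair,
    lgcn_forward,
    reconstruction_loss,
    train,
    wasserstein_loss,
    EmbeddingPair,
)
from slicealign._nn import MLP, Adam


def test_wasserstein_loss_examples():
    assert wasserstein_loss([1.0, 2.0], [2.0, 1.0]) == 0.0
    assert wasserstein_loss([1.0, 1.0], [0.0]) == 1.0
    base = wasserstein_loss([0.3, 0.7], [0.1])
    assert wasserstein_loss([0.9, 2.1], [0.3]) == pytest.approx(3 * base)
    with pytest.raises(ValueError):
        wasserstein_loss([], [1.0])


def test_dynamic_clip_examples():
    i1, i2 = dynamic_clip([3.0, 1.0, 2.0], [3.0, 1.0, 2.0], c=1.0)
    assert set(i1) == set(i2) == {0, 1, 2}
    i1, _ = dynamic_clip([3.0, 1.0, 2.0], [0.0], c=2 / 3)
    assert set(i1) == {1, 2}
    _, i2 = dynamic_clip([0.0], [3.0, 1.0, 2.0], c=1 / 3)
    assert set(i2) == {0}
    # c*N < 1 keeps one element
    i1, i2 = dynamic_clip([5.0, 4.0], [4.0, 5.0], c=0.1)
    assert list(i1) == [1] and list(i2) == [1]


def test_dynamic_clip_matches_sort_oracle():
    rng = np.random.default_rng(0)
    for _ in range(100):
        n1, n2 = rng.integers(1, 101, size=2)
        d1 = rng.choice([0.0, 0.25, 0.5, 1.0], size=n1)  # force ties
        d2 = rng.standard_normal(n2)
        c = float(rng.uniform(0.05, 1.0))
        i1, i2 = dynamic_clip(d1, d2, c)
        k1, k2 = max(1, int(np.floor(c * n1))), max(1, int(np.floor(c * n2)))
        o1 = np.lexsort((np.arange(n1), d1))[:k1]
        o2 = np.lexsort((np.arange(n2), -d2))[:k2]
        np.testing.assert_array_equal(np.sort(i1), np.sort(o1))
        np.testing.assert_array_equal(np.sort(i2), np.sort(o2))
        np.testing.assert_array_equal(i1, o1)  # same order too (ties by index)


class _StubR:
    """Reconstructor stub returning a fixed offset of the embedding."""

    def __init__(self, offset):
        self.offset = np.asarray(offset, float)

    def forward(self, Z):
        return np.asarray(Z, float) + self.offset


def test_reconstruction_loss_examples():
    Z = np.array([[1.0, 2.0]])
    perfect = reconstruction_loss(Z, Z, Z, Z, _StubR([0.0, 0.0]))
    assert perfect == 0.0
    # residual (3, 4) per cell in each slice -> norm 5 + 5
    off = _StubR([3.0, 4.0])
    assert reconstruction_loss(Z, Z, Z, Z, off) == pytest.approx(10.0)
    double = _StubR([6.0, 8.0])
    assert reconstruction_loss(Z, Z, Z, Z, double) == pytest.approx(20.0)


def _toy_pair(n=40, seed=0, **cfg_kw):
    rng = np.random.default_rng(seed)
    coords = rng.uniform(size=(n, 2))
    g = build_knn_graph(coords, 4)
    X = rng.standard_normal((n, 6))
    ep = EmbeddingPair(X, X.copy())
    h1, h2 = holistic_pair(ep, g, g, L=2)
    cfg = AlignConfig(
        steps=60, embed_dim=8, hidden=16, embed_hidden=32, seed=1,
        early_stop=False, **cfg_kw,
    )
    return h1, h2, cfg


def test_self_alignment_embeddings_match():
    h1, h2, cfg = _toy_pair()
    model = train(h1, h2, cfg)
    Z1, Z2 = model.project(h1.Xt), model.project(h2.Xt)
    cos = np.einsum("ij,ij->i", Z1, Z2) / (
        np.linalg.norm(Z1, axis=1) * np.linalg.norm(Z2, axis=1)
    )
    assert cos.mean() > 0.99


def test_training_is_bit_reproducible():
    h1, h2, cfg = _toy_pair()
    Za = train(h1, h2, cfg).project(h1.Xt)
    Zb = train(h1, h2, cfg).project(h1.Xt)
    assert Za.tobytes() == Zb.tobytes()


def test_no_discriminator_mode_trains_reconstruction_only():
    h1, h2, cfg = _toy_pair(ablate="no_discriminator")
    model = train(h1, h2, cfg)
    assert np.isfinite(model.project(h1.Xt)).all()
    assert np.all(np.isnan(model.history.loss_w))
    assert model.history.loss_r[-1] < model.history.loss_r[0]


def test_reconstruction_loss_trailing_average_non_increasing():
    h1, h2, cfg = _toy_pair()
    model = train(h1, h2, cfg)
    lr = np.asarray(model.history.loss_r)
    w = 20
    first = lr[:w].mean()
    last = lr[-w:].mean()
    assert last <= first + 1e-6


def test_one_discriminator_step_increases_wasserstein_loss():
    """Finite-difference check: the critic update is an ascent direction."""
    rng = np.random.default_rng(3)
    Z1 = rng.standard_normal((30, 5)) + 1.0
    Z2 = rng.standard_normal((25, 5)) - 1.0
    f_D = MLP(5, 12, 1, np.random.default_rng(0), dtype=np.float64)

    def lw():
        return wasserstein_loss(f_D.forward(Z1).ravel(), f_D.forward(Z2).ravel())

    before = lw()
    c1, c2 = {}, {}
    d1 = f_D.forward(Z1, c1)
    d2 = f_D.forward(Z2, c2)
    g1 = np.full((30, 1), -1.0 / 30)  # minimise -L_W with c = 1
    g2 = np.full((25, 1), 1.0 / 25)
    f_D.zero_grad()
    f_D.backward(g1, c1)
    f_D.backward(g2, c2)
    Adam(f_D.params(), lr=1e-3).step(f_D.grads())
    assert lw() > before


def test_config_validation():
    with pytest.raises(ValueError):
        AlignConfig(clip_ratio=0.0)
    with pytest.raises(ValueError):
        AlignConfig(alpha=1.0)
    with pytest.raises(ValueError):
        AlignConfig(ablate="bogus")


def test_width_mismatch_rejected():
    h1, h2, cfg = _toy_pair()
    import scipy.sparse as sp

    h3 = lgcn_forward(sp.identity(h2.n, format="csr"), h2.Xt[:, :4], L=0)
    with pytest.raises(ValueError):
        train(h1, h3, cfg)
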