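"""Adversarial alignment of holistic representations.

Three networks are trained jointly on the concatenated LGCN features of the
two slices:

* a shared projector ``f_Z: (L+1)M -> P`` mapping both slices into a common
  alignment space (``Z1 = f_Z(X~1)``, ``Z2 = f_Z(X~2)``);
* a Wasserstein critic ``f_D: P -> scalar`` whose clipped mean difference

      L_W = mean_{i in V1'} f_D(z1_i) - mean_{j in V2'} f_D(z2_j)

  estimates the Wasserstein distance between the two embedding clouds;
* a reconstructor ``f_R: P -> M`` whose loss

      L_R = mean_i ||f_R(z1_i) - x1_i|| + mean_j ||f_R(z2_j) - x2_j||

  (per-cell Euclidean norm against the un-propagated block-0 features)
  prevents the embeddings from collapsing to a point.

*Dynamic clipping*: each step, the critic's own outputs select the fraction
``c`` of slice-1 cells with the smallest scores and of slice-2 cells with
the largest scores — the pairs currently judged closest across slices.
Only these anchors enter L_W, so structurally distinct regions are not
forcibly aligned (anti over-alignment).

Optimisation alternates a critic ascent step on ``alpha * L_W`` with a
generator descent step on ``alpha * L_W + (1 - alpha) * L_R`` over
``f_Z, f_R`` (full-batch Adam).  The critic's Lipschitz constraint is
enforced by weight clipping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._nn import MLP, Adam
from .lgcn import HolisticRepresentation

__all__ = [
    "AlignConfig",
    "AlignmentModel",
    "TrainState",
    "wasserstein_loss",
    "dynamic_clip",
    "reconstruction_loss",
    "train",
]


@dataclass
class AlignConfig:
    """Hyperparameters of the alignment model.

    ``alpha`` balances adversarial alignment against reconstruction;
    ``clip_ratio`` is the dynamic clipping fraction c in (0, 1];
    ``embed_hidden`` is the projector's internal width and ``hidden`` the
    critic/reconstructor width; ``weight_clip`` bounds critic weights
    (Lipschitz control).  ``ablate`` may be ``"none"``,
    ``"no_discriminator"`` (reconstruction-only, the alpha = 0 path) or
    ``"no_lgcn"`` (handled upstream by forcing L = 0).
    """

    alpha: float = 0.5
    clip_ratio: float = 0.6
    lr: float = 1e-4
    steps: int = 500
    seed: int = 0
    embed_dim: int = 50  # P
    hidden: int = 256
    embed_hidden: int = 2048
    weight_clip: float = 0.1
    ablate: str = "none"
    early_stop: bool = True
    early_stop_window: int = 50
    early_stop_tol: float = 1e-4
    min_steps: int = 100

    def __post_init__(self) -> None:
        if not 0 < self.clip_ratio <= 1:
            raise ValueError("clip_ratio must be in (0, 1]")
        if not 0 <= self.alpha < 1:
            raise ValueError("alpha must be in [0, 1)")
        if self.ablate not in ("none", "no_discriminator", "no_lgcn"):
            raise ValueError(f"unknown ablation {self.ablate!r}")


@dataclass
class TrainState:
    """Per-step loss curves and anchor-set sizes."""

    loss_w: list[float] = field(default_factory=list)
    loss_r: list[float] = field(default_factory=list)
    n_anchor_1: int = 0
    n_anchor_2: int = 0

    @property
    def n_steps(self) -> int:
        return len(self.loss_r)


@dataclass
class AlignmentModel:
    """Trained projector/critic/reconstructor triple."""

    f_Z: MLP
    f_D: MLP
    f_R: MLP
    cfg: AlignConfig
    history: TrainState = field(default_factory=TrainState)

    def project(self, Xt: np.ndarray) -> np.ndarray:
        """Map holistic features into the alignment space (rows -> Z)."""
        return np.asarray(self.f_Z.forward(np.asarray(Xt)), dtype=float)

    def discriminate(self, Z: np.ndarray) -> np.ndarray:
        return np.asarray(self.f_D.forward(np.asarray(Z)), dtype=float).ravel()

    def reconstruct(self, Z: np.ndarray) -> np.ndarray:
        return np.asarray(self.f_R.forward(np.asarray(Z)), dtype=float)


def wasserstein_loss(d1: np.ndarray, d2: np.ndarray) -> float:
    """Mean critic score on slice-1 anchors minus mean on slice-2 anchors."""
    d1 = np.asarray(d1, dtype=float).ravel()
    d2 = np.asarray(d2, dtype=float).ravel()
    if d1.size == 0 or d2.size == 0:
        raise ValueError("empty anchor selection")
    return float(d1.mean() - d2.mean())


def _clip_count(c: float, n: int) -> int:
    return max(1, int(np.floor(c * n)))


def dynamic_clip(d1: np.ndarray, d2: np.ndarray, c: float) -> tuple[np.ndarray, np.ndarray]:
    """Anchor selection from critic outputs.

    Returns indices of the ``floor(c * N1)`` smallest entries of ``d1`` and
    the ``floor(c * N2)`` largest entries of ``d2`` (at least one each);
    ties are broken by lower index.
    """
    if not 0 < c <= 1:
        raise ValueError("c must be in (0, 1]")
    d1 = np.asarray(d1, dtype=float).ravel()
    d2 = np.asarray(d2, dtype=float).ravel()
    k1 = _clip_count(c, d1.size)
    k2 = _clip_count(c, d2.size)
    i1 = np.argsort(d1, kind="stable")[:k1]
    i2 = np.argsort(-d2, kind="stable")[:k2]
    return i1, i2


def _residual_norms(R: np.ndarray, X: np.ndarray) -> np.ndarray:
    return np.linalg.norm(np.asarray(R, float) - np.asarray(X, float), axis=1)


def reconstruction_loss(
    Z1: np.ndarray, Z2: np.ndarray, X1: np.ndarray, X2: np.ndarray, f_R: MLP
) -> float:
    """Within-slice mean Euclidean reconstruction error, summed over slices."""
    r1 = _residual_norms(f_R.forward(np.asarray(Z1)), X1)
    r2 = _residual_norms(f_R.forward(np.asarray(Z2)), X2)
    return float(r1.mean() + r2.mean())


def train(
    h1: HolisticRepresentation,
    h2: HolisticRepresentation,
    cfg: AlignConfig | None = None,
) -> AlignmentModel:
    """Train the alignment model on a pair of holistic representations.

    Alternates one critic step (ascent on ``alpha * L_W`` over the dynamic
    anchor sets, followed by weight clipping) with one generator step
    (descent on ``alpha * L_W + (1 - alpha) * L_R``); the anchor sets are
    recomputed each step from the critic's outputs on all cells.
    Deterministic given ``cfg.seed``.  Raises ``RuntimeError`` on divergence
    (non-finite loss).
    """
    cfg = cfg or AlignConfig()
    if h1.M != h2.M or h1.Xt.shape[1] != h2.Xt.shape[1]:
        raise ValueError("representations differ in width")
    rng = np.random.default_rng(cfg.seed)
    d_in, M, P = h1.Xt.shape[1], h1.M, cfg.embed_dim
    f_Z = MLP(d_in, cfg.embed_hidden, P, rng)
    f_D = MLP(P, cfg.hidden, 1, rng)
    f_R = MLP(P, cfg.hidden, M, rng)
    opt_Z = Adam(f_Z.params(), lr=cfg.lr)
    opt_D = Adam(f_D.params(), lr=cfg.lr)
    opt_R = Adam(f_R.params(), lr=cfg.lr)

    no_disc = cfg.ablate == "no_discriminator"
    alpha = 0.0 if no_disc else cfg.alpha
    dtype = f_Z.dtype
    Xt1 = np.asarray(h1.Xt, dtype=dtype)
    Xt2 = np.asarray(h2.Xt, dtype=dtype)
    X1 = np.asarray(h1.blocks[0], dtype=dtype)
    X2 = np.asarray(h2.blocks[0], dtype=dtype)
    N1, N2 = Xt1.shape[0], Xt2.shape[0]
    state = TrainState(
        n_anchor_1=_clip_count(cfg.clip_ratio, N1),
        n_anchor_2=_clip_count(cfg.clip_ratio, N2),
    )
    model = AlignmentModel(f_Z, f_D, f_R, cfg, state)
    total_hist: list[float] = []

    for step in range(cfg.steps):
        # ---- critic step: ascend alpha * L_W over f_D -------------------
        if alpha > 0:
            Z1 = f_Z.forward(Xt1)
            Z2 = f_Z.forward(Xt2)
            cd1, cd2 = {}, {}
            d1 = f_D.forward(Z1, cd1).ravel()
            d2 = f_D.forward(Z2, cd2).ravel()
            i1, i2 = dynamic_clip(d1, d2, cfg.clip_ratio)
            g1 = np.zeros((N1, 1), dtype=dtype)
            g2 = np.zeros((N2, 1), dtype=dtype)
            g1[i1, 0] = -alpha / i1.size  # minimise -alpha * L_W
            g2[i2, 0] = alpha / i2.size
            f_D.zero_grad()
            f_D.backward(g1, cd1)
            f_D.backward(g2, cd2)
            opt_D.step(f_D.grads())
            f_D.clip_weights(cfg.weight_clip)

        # ---- generator step: descend alpha * L_W + (1-alpha) * L_R -----
        cz1, cz2 = {}, {}
        Z1 = f_Z.forward(Xt1, cz1)
        Z2 = f_Z.forward(Xt2, cz2)
        cr1, cr2 = {}, {}
        R1 = f_R.forward(Z1, cr1)
        R2 = f_R.forward(Z2, cr2)
        res1 = R1 - X1
        res2 = R2 - X2
        n1 = np.linalg.norm(res1, axis=1)
        n2 = np.linalg.norm(res2, axis=1)
        loss_r = float(n1.mean() + n2.mean())
        dR1 = (1 - alpha) / N1 * res1 / np.maximum(n1, 1e-12)[:, None]
        dR2 = (1 - alpha) / N2 * res2 / np.maximum(n2, 1e-12)[:, None]
        f_R.zero_grad()
        dZ1 = f_R.backward(dR1, cr1)
        dZ2 = f_R.backward(dR2, cr2)

        loss_w = np.nan
        if alpha > 0:
            cd1, cd2 = {}, {}
            d1 = f_D.forward(Z1, cd1).ravel()
            d2 = f_D.forward(Z2, cd2).ravel()
            i1, i2 = dynamic_clip(d1, d2, cfg.clip_ratio)
            loss_w = wasserstein_loss(d1[i1], d2[i2])
            g1 = np.zeros((N1, 1), dtype=dtype)
            g2 = np.zeros((N2, 1), dtype=dtype)
            g1[i1, 0] = alpha / i1.size
            g2[i2, 0] = -alpha / i2.size
            f_D.zero_grad()  # critic params frozen; only its input grad is used
            dZ1 += f_D.backward(g1, cd1)
            dZ2 += f_D.backward(g2, cd2)

        f_Z.zero_grad()
        f_Z.backward(dZ1, cz1)
        f_Z.backward(dZ2, cz2)
        opt_Z.step(f_Z.grads())
        opt_R.step(f_R.grads())

        state.loss_r.append(loss_r)
        state.loss_w.append(float(loss_w))
        total = alpha * (0.0 if np.isnan(loss_w) else loss_w) + (1 - alpha) * loss_r
        total_hist.append(total)
        if not np.isfinite(loss_r) or (alpha > 0 and not np.isfinite(loss_w)):
            raise RuntimeError(
                f"training diverged at step {step}: L_W={loss_w}, L_R={loss_r}"
            )
        if cfg.early_stop and step + 1 >= max(cfg.min_steps, 2 * cfg.early_stop_window):
            w = cfg.early_stop_window
            recent = np.mean(total_hist[-w:])
            prev = np.mean(total_hist[-2 * w : -w])
            scale = max(abs(prev), 1e-8)
            if abs(recent - prev) / scale < cfg.early_stop_tol:
                break
    return model
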