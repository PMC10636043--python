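"""Coordinate matching: affine registration of slice 2 onto slice 1.

Before candidate matching, the two coordinate frames are roughly
superposed by an affine transform — estimated landmark-free with
multi-start ICP (iterative closest point) by default, supplied manually
(scale/rotate/translate), or loaded from an external 3x3 matrix.  The
fitted motion is rigid plus optional isotropic scale; non-rigid
deformation is handled downstream in embedding space, never by warping
coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "AffineTransform",
    "manual_transform",
    "rigid_fit",
    "icp_register",
    "apply_transform",
]


@dataclass
class AffineTransform:
    """2-D homogeneous transform (last row [0, 0, 1]).

    Stored in the column-vector convention ``p' = M p``; ``apply`` acts on
    coordinate matrices with cells as rows.
    """

    matrix: np.ndarray
    source: str = "manual"  # {"icp", "manual", "external"}

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (3, 3):
            raise ValueError("affine matrix must be 3 x 3")
        if not np.allclose(self.matrix[2], [0, 0, 1]):
            raise ValueError("last row must be [0, 0, 1]")

    @property
    def rotation_deg(self) -> float:
        """Rotation angle of the upper 2x2 block (degrees, (-180, 180])."""
        a = self.matrix[:2, :2]
        return float(np.degrees(np.arctan2(a[1, 0], a[0, 0])))

    @property
    def scale(self) -> float:
        return float(np.sqrt(abs(np.linalg.det(self.matrix[:2, :2]))))

    def apply(self, S: np.ndarray) -> np.ndarray:
        S = np.asarray(S, dtype=float)
        return S @ self.matrix[:2, :2].T + self.matrix[:2, 2]

    def inverse(self) -> "AffineTransform":
        if abs(np.linalg.det(self.matrix)) < 1e-300:
            raise ValueError("transform is singular")
        return AffineTransform(np.linalg.inv(self.matrix), source=self.source)

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """self after other (apply ``other`` first)."""
        return AffineTransform(self.matrix @ other.matrix, source=self.source)


def apply_transform(S: np.ndarray, t: AffineTransform) -> np.ndarray:
    """Transform an N x 2 coordinate matrix."""
    if abs(np.linalg.det(t.matrix)) < 1e-300:
        raise ValueError("transform is singular")
    return t.apply(S)


def _translation(v) -> np.ndarray:
    m = np.eye(3)
    m[:2, 2] = v
    return m


def _rotation(deg: float) -> np.ndarray:
    th = np.radians(deg)
    c, s = np.cos(th), np.sin(th)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def manual_transform(
    rotate_deg: float = 0.0,
    scale: float = 1.0,
    translate=(0.0, 0.0),
    center=(0.0, 0.0),
) -> AffineTransform:
    """Compose scale -> rotate -> translate about ``center``."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    sc = np.diag([scale, scale, 1.0])
    m = (
        _translation(np.asarray(center) + np.asarray(translate))
        @ _rotation(rotate_deg)
        @ sc
        @ _translation(-np.asarray(center))
    )
    return AffineTransform(m, source="manual")


def rigid_fit(src: np.ndarray, dst: np.ndarray, with_scale: bool = True) -> AffineTransform:
    """Closed-form least-squares rigid (+ isotropic scale) fit src -> dst.

    The Umeyama solution: rotation from the SVD of the cross-covariance with
    a determinant guard against reflections.
    """
    src = np.asarray(src, float)
    dst = np.asarray(dst, float)
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    sc, dc = src - mu_s, dst - mu_d
    H = sc.T @ dc / len(src)
    U, sv, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, d])
    R = Vt.T @ D @ U.T
    if with_scale:
        var_s = (sc**2).sum() / len(src)
        s = float((sv * np.diag(D)).sum() / var_s) if var_s > 0 else 1.0
    else:
        s = 1.0
    m = np.eye(3)
    m[:2, :2] = s * R
    m[:2, 2] = mu_d - s * R @ mu_s
    return AffineTransform(m, source="icp")


def icp_register(
    S1: np.ndarray,
    S2: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-6,
    with_scale: bool = True,
    n_starts: int = 12,
    max_points: int = 5000,
    seed: int = 0,
    full_output: bool = False,
):
    """Multi-start ICP registering S2 onto S1 (returns t with t(S2) ~ S1).

    ICP is a local method, so ``n_starts`` initial rotations on a coarse
    angular grid (about the centroids, after centroid alignment) are tried
    and the lowest-residual solution kept.  Each start alternates
    nearest-neighbour correspondence in S1 with a closed-form rigid
    (+ isotropic scale) refit until the mean residual changes by less than
    ``tol``; the residual is non-increasing across iterations.  Point sets
    larger than ``max_points`` are subsampled once (seeded) for the
    correspondence search and the winning transform is refit on the
    subsample correspondences.
    """
    S1 = np.asarray(S1, float)
    S2 = np.asarray(S2, float)
    if len(S1) < 3 or len(S2) < 3:
        raise ValueError("ICP needs at least 3 points per slice")
    rng = np.random.default_rng(seed)
    S2s = S2
    if len(S2) > max_points:
        S2s = S2[rng.choice(len(S2), max_points, replace=False)]
    S1s = S1
    if len(S1) > max_points:
        S1s = S1[rng.choice(len(S1), max_points, replace=False)]
    tree = cKDTree(S1s)
    mu1, mu2 = S1s.mean(axis=0), S2s.mean(axis=0)

    best: tuple[float, AffineTransform, list[float]] | None = None
    angles = np.arange(n_starts) * (360.0 / n_starts)
    for ang in angles:
        t = AffineTransform(
            _translation(mu1) @ _rotation(ang) @ _translation(-mu2), source="icp"
        )
        prev = np.inf
        converged = False
        residuals: list[float] = []
        for _ in range(max_iter):
            moved = t.apply(S2s)
            dist, nn = tree.query(moved)
            t = rigid_fit(S2s, S1s[nn], with_scale=with_scale)
            # RMS residual: monotone under the alternation of NN
            # correspondence and least-squares refit
            resid = float(
                np.sqrt(np.mean(np.sum((t.apply(S2s) - S1s[nn]) ** 2, axis=1)))
            )
            residuals.append(resid)
            if abs(prev - resid) < tol:
                converged = True
                break
            prev = resid
        if not converged:
            warnings.warn(
                f"ICP start {ang:.0f} deg did not converge in {max_iter} iterations",
                stacklevel=2,
            )
        if best is None or resid < best[0]:
            best = (resid, t, residuals)
    if full_output:
        return best[1], best[2]
    return best[1]
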