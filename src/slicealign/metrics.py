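"""Evaluation statistics for slice alignments.

Implements the benchmark metrics: ground-truth accuracy for duplicated
slices, cell-type/region contingency accuracies (with "joint accuracy" =
both matched), micro/macro F1 scores, Procrustes recovery of the applied
rotation, and the neighbourhood-preservation edge score.  The edge score
is known to be gameable: pairings that permute structurally equivalent
cells preserve every neighbour relation and tie the correct pairing —
ground-truth accuracy separates them.

All accuracies are computed on *best* matches (minimal p-value, ties by
maximal cosine), one partner per evaluated cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score

from .graph import SpatialGraph
from .io import NA_LABEL

__all__ = [
    "ContingencyReport",
    "ground_truth_accuracy",
    "label_accuracy",
    "f1_scores",
    "procrustes_rotation",
    "edge_score",
]


def ground_truth_accuracy(best_targets: np.ndarray, truth: np.ndarray | None = None) -> float:
    """Fraction of cells whose best match equals the known partner.

    In the duplicate-slice setting cell i's true partner is i, which is the
    default ``truth``.
    """
    best_targets = np.asarray(best_targets, dtype=int)
    if truth is None:
        truth = np.arange(best_targets.size)
    return float(np.mean(best_targets == np.asarray(truth, dtype=int)))


@dataclass
class ContingencyReport:
    """Joint 2x2 contingency of cell-type / region matching plus confusions.

    ``joint`` holds the four proportions over evaluated cells (rows:
    type matched yes/no; columns: region matched yes/no); they sum to 1.
    ``joint_accuracy`` is the (yes, yes) corner.
    """

    joint: pd.DataFrame
    type_confusion: pd.DataFrame
    region_confusion: pd.DataFrame
    n_evaluated: int

    @property
    def joint_accuracy(self) -> float:
        return float(self.joint.loc["type_match", "region_match"])

    @property
    def type_accuracy(self) -> float:
        return float(self.joint.loc["type_match"].sum())

    @property
    def region_accuracy(self) -> float:
        return float(self.joint["region_match"].sum())


def _confusion(true_lab: np.ndarray, pred_lab: np.ndarray) -> pd.DataFrame:
    t = pd.Series(true_lab, name="true")
    p = pd.Series(pred_lab, name="matched")
    return pd.crosstab(t, p)


def label_accuracy(
    sources: np.ndarray,
    targets: np.ndarray,
    type1: np.ndarray,
    type2: np.ndarray,
    region1: np.ndarray | None = None,
    region2: np.ndarray | None = None,
) -> ContingencyReport:
    """Contingency of label agreement between matched cells.

    ``sources``/``targets`` are the best-match pairs (indices into slice 1
    and slice 2).  Cells with the NA sentinel in any required label are
    excluded; label vocabularies may differ, in which case a mismatch is
    simply counted as incorrect.
    """
    sources = np.asarray(sources, dtype=int)
    targets = np.asarray(targets, dtype=int)
    t1 = np.asarray(type1, dtype=object)[sources]
    t2 = np.asarray(type2, dtype=object)[targets]
    keep = (t1 != NA_LABEL) & (t2 != NA_LABEL)
    if region1 is not None and region2 is not None:
        r1 = np.asarray(region1, dtype=object)[sources]
        r2 = np.asarray(region2, dtype=object)[targets]
        keep &= (r1 != NA_LABEL) & (r2 != NA_LABEL)
    else:
        r1 = r2 = None
    t1, t2 = t1[keep], t2[keep]
    n = int(keep.sum())
    type_ok = t1 == t2
    if r1 is not None:
        r1, r2 = r1[keep], r2[keep]
        region_ok = r1 == r2
    else:
        region_ok = np.ones(n, dtype=bool)
    joint = pd.DataFrame(
        [
            [np.mean(type_ok & region_ok), np.mean(type_ok & ~region_ok)],
            [np.mean(~type_ok & region_ok), np.mean(~type_ok & ~region_ok)],
        ],
        index=["type_match", "type_mismatch"],
        columns=["region_match", "region_mismatch"],
    )
    return ContingencyReport(
        joint=joint,
        type_confusion=_confusion(t1, t2),
        region_confusion=_confusion(r1, r2) if r1 is not None else pd.DataFrame(),
        n_evaluated=n,
    )


def f1_scores(
    sources: np.ndarray,
    targets: np.ndarray,
    type1: np.ndarray,
    type2: np.ndarray,
    region1: np.ndarray | None = None,
    region2: np.ndarray | None = None,
) -> dict[str, float]:
    """Micro/macro F1 of type, region and joint matching.

    Matching is treated as a classification of each slice-1 cell into the
    label of its matched partner.  Macro averages over the classes present
    in slice 1 only (heterogeneous annotations make the union ill-defined);
    a class never predicted contributes F1 = 0.
    """
    sources = np.asarray(sources, dtype=int)
    targets = np.asarray(targets, dtype=int)
    out: dict[str, float] = {}
    tasks = {"type": (type1, type2)}
    if region1 is not None and region2 is not None:
        tasks["region"] = (region1, region2)
        tasks["joint"] = (
            np.char.add(np.char.add(np.asarray(type1, str), "|"), np.asarray(region1, str)),
            np.char.add(np.char.add(np.asarray(type2, str), "|"), np.asarray(region2, str)),
        )
    for name, (lab1, lab2) in tasks.items():
        y_true = np.asarray(lab1, dtype=object)[sources]
        y_pred = np.asarray(lab2, dtype=object)[targets]
        keep = np.array(
            [NA_LABEL not in str(a).split("|") and NA_LABEL not in str(b).split("|")
             for a, b in zip(y_true, y_pred)]
        )
        y_true, y_pred = y_true[keep].astype(str), y_pred[keep].astype(str)
        classes = sorted(set(y_true))
        out[f"{name}_micro_f1"] = float(
            f1_score(y_true, y_pred, labels=classes, average="micro", zero_division=0)
        )
        out[f"{name}_macro_f1"] = float(
            f1_score(y_true, y_pred, labels=classes, average="macro", zero_division=0)
        )
    return out


def procrustes_rotation(S1m: np.ndarray, S2m: np.ndarray) -> tuple[float, float, bool]:
    """Optimal corrective rotation between matched coordinate pairs.

    Solves the orthogonal Procrustes problem on the centred pairs: the
    rotation R (det = +1) minimising ``||S1c - S2c R^T||_F``, i.e. the
    rotation carrying slice-2 positions onto their slice-1 partners.
    Returns ``(angle_deg, rms_residual, reflection)`` where ``reflection``
    is True when the unconstrained optimum was a reflection (det < 0) and
    the residual is correspondingly large.
    """
    S1m = np.asarray(S1m, float)
    S2m = np.asarray(S2m, float)
    if len(S1m) < 2 or len(S1m) != len(S2m):
        raise ValueError("need >= 2 matched coordinate pairs")
    c1, c2 = S1m - S1m.mean(axis=0), S2m - S2m.mean(axis=0)
    if np.linalg.matrix_rank(np.vstack([c1, c2])) < 2:
        import warnings

        warnings.warn("degenerate (collinear) coordinates in Procrustes fit", stacklevel=2)
    H = c2.T @ c1
    U, _, Vt = np.linalg.svd(H)
    det = np.linalg.det(Vt.T @ U.T)
    reflection = bool(det < 0)
    D = np.diag([1.0, np.sign(det) if det != 0 else 1.0])
    R = Vt.T @ D @ U.T
    angle = float(np.degrees(np.arctan2(R[1, 0], R[0, 0])))
    resid = float(np.sqrt(np.mean(np.sum((c1 - c2 @ R.T) ** 2, axis=1))))
    return angle, resid, reflection


def rotation_error_deg(estimated: float, applied: float) -> float:
    """Absolute angular deviation on the circle, in [0, 180]."""
    d = (estimated - applied + 180.0) % 360.0 - 180.0
    return abs(float(d))


def edge_score(
    sources: np.ndarray,
    targets: np.ndarray,
    g1: SpatialGraph,
    g2: SpatialGraph,
) -> float:
    """Neighbourhood preservation of a pairing: +1 per preserved neighbour
    relation, -1 per broken one, averaged over evaluated slice-1 cells.

    For each matched cell n with partner n', every matched neighbour m of n
    in graph 1 contributes +1 when the partners n', m' are adjacent in
    graph 2 and -1 otherwise.  Cells without a match (and unmatched
    neighbours) are skipped, and the normalisation counts evaluated cells
    only.
    """
    sources = np.asarray(sources, dtype=int)
    targets = np.asarray(targets, dtype=int)
    partner = np.full(g1.n, -1, dtype=int)
    partner[sources] = targets
    A2 = g2.A.tocsr()
    total = 0.0
    n_eval = 0
    for n, npr in zip(sources, targets):
        nbrs = g1.neighbors(n)
        mprs = partner[nbrs]
        mprs = mprs[mprs >= 0]
        if mprs.size == 0 and nbrs.size > 0:
            continue
        n_eval += 1
        row = A2.indices[A2.indptr[npr] : A2.indptr[npr + 1]]
        hits = np.isin(mprs, row)
        total += hits.sum() - (~hits).sum()
    if n_eval == 0:
        return float("nan")
    return float(total / n_eval)
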