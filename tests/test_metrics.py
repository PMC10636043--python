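import numpy as np
import pytest

from slicealign import (
    build_radius_graph,
    edge_score,
    f1_scores,
    ground_truth_accuracy,
    label_accuracy,
    manual_transform,
    procrustes_rotation,
)
from slicealign.metrics import rotation_error_deg


def test_ground_truth_accuracy_counts():
    assert ground_truth_accuracy([0, 1, 2, 3]) == 1.0
    assert ground_truth_accuracy([1, 2, 3, 0]) == 0.0
    assert ground_truth_accuracy([0, 1, 2, 0]) == 0.75


def test_label_accuracy_identity_matching():
    types = np.array(["a", "a", "b", "b"], dtype=object)
    regions = np.array(["r1", "r2", "r1", "r2"], dtype=object)
    rep = label_accuracy(np.arange(4), np.arange(4), types, types, regions, regions)
    assert rep.joint_accuracy == 1.0
    assert float(rep.joint.to_numpy().sum()) == pytest.approx(1.0)


def test_label_accuracy_type_preserving_region_scrambling():
    # two regions, one cell type; pairing swaps cells across regions
    types = np.array(["a", "a", "a", "a"], dtype=object)
    regions = np.array(["r1", "r1", "r2", "r2"], dtype=object)
    targets = np.array([2, 3, 0, 1])  # same type, wrong region, for every cell
    rep = label_accuracy(np.arange(4), targets, types, types, regions, regions)
    assert rep.joint.loc["type_match", "region_mismatch"] == 1.0
    assert rep.joint_accuracy == 0.0
    assert rep.type_accuracy == 1.0 and rep.region_accuracy == 0.0


def test_f1_perfect_matching():
    types = np.array(["a", "b", "c"] * 4, dtype=object)
    out = f1_scores(np.arange(12), np.arange(12), types, types)
    assert out["type_micro_f1"] == 1.0 and out["type_macro_f1"] == 1.0


def test_f1_minority_class_always_wrong_matches_hand_confusion():
    # 90 majority cells matched correctly, 10 minority cells matched to the
    # majority class; hand-computed confusion: micro F1 = 0.9,
    # macro F1 = mean(F1_maj = 2*0.9/1.9, F1_min = 0)
    types1 = np.array(["maj"] * 90 + ["min"] * 10, dtype=object)
    types2 = np.array(["maj"] * 100, dtype=object)
    out = f1_scores(np.arange(100), np.arange(100), types1, types2)
    assert out["type_micro_f1"] == pytest.approx(0.9)
    assert out["type_macro_f1"] == pytest.approx((2 * 0.9 / 1.9) / 2)
    # errors concentrated in the rare class push macro below micro
    assert out["type_macro_f1"] < out["type_micro_f1"]


@pytest.mark.parametrize("angle", [0.0, 30.0, 60.0, 120.0])
def test_procrustes_recovers_manual_rotation_exactly(angle):
    rng = np.random.default_rng(0)
    S2 = rng.uniform(size=(25, 2))
    t = manual_transform(angle, 1.0, center=(0.5, 0.5))
    S1 = t.apply(S2)  # S1 is S2 rotated by `angle`
    est, resid, refl = procrustes_rotation(S1, S2)
    assert rotation_error_deg(est, angle) < 1e-9
    assert resid < 1e-12 and not refl


def test_procrustes_identity_and_reflection():
    rng = np.random.default_rng(1)
    S = rng.uniform(size=(10, 2))
    est, resid, refl = procrustes_rotation(S, S)
    assert abs(est) < 1e-9 and resid < 1e-12 and not refl
    mirrored = S * [-1.0, 1.0]
    est, resid, refl = procrustes_rotation(mirrored, S)
    assert refl
    assert resid > 0.01


def test_procrustes_warns_on_collinear_input():
    line = np.column_stack([np.arange(5.0), np.zeros(5)])
    with pytest.warns(UserWarning, match="degenerate"):
        procrustes_rotation(line, line)


def _pair_cluster_graph():
    """Disjoint vertical pairs: two structurally identical far-apart pairs
    plus a third one, radius graph connecting only within pairs."""
    coords = np.array(
        [[0.0, 0], [0, 1],      # pair A: cells 0, 1
         [10.0, 0], [10, 1],    # pair B: cells 2, 3 (identical shape)
         [20.0, 0], [20, 1]]    # pair C
    )
    return build_radius_graph(coords, 1.5)


def test_edge_score_identity_equals_average_degree():
    g = _pair_cluster_graph()
    ident = np.arange(6)
    assert edge_score(ident, ident, g, g) == pytest.approx(1.0)  # degree 1 each


def test_edge_score_equal_for_correct_and_swapped_pairing():
    """The known caveat: swapping two structurally equivalent 2-cell groups
    (4 mismatched cells) preserves every neighbour relation, so the edge
    score ties the correct pairing while ground-truth accuracy separates
    them."""
    g = _pair_cluster_graph()
    ident = np.arange(6)
    swapped = np.array([2, 3, 0, 1, 4, 5])  # pair A <-> pair B
    s_correct = edge_score(ident, ident, g, g)
    s_swapped = edge_score(ident, swapped, g, g)
    assert s_correct == pytest.approx(s_swapped)
    assert ground_truth_accuracy(ident) == 1.0
    assert ground_truth_accuracy(swapped) == pytest.approx(2 / 6)


def test_edge_score_reversed_4_cycle_preserves_score(unit_square):
    g = build_radius_graph(unit_square, 1.0)
    ident = np.arange(4)
    reversed_cycle = np.array([0, 3, 2, 1])  # traverse the cycle backwards
    assert edge_score(ident, reversed_cycle, g, g) == pytest.approx(
        edge_score(ident, ident, g, g)
    )


def test_edge_score_invariant_under_simultaneous_relabeling():
    from slicealign.graph import SpatialGraph
    import scipy.sparse as sp

    g = _pair_cluster_graph()
    rng = np.random.default_rng(3)
    perm = rng.permutation(6)
    P = np.eye(6)[perm]
    A2 = sp.csr_matrix(P @ g.A.toarray() @ P.T)
    g_perm = SpatialGraph(A2, mode="radius", param=g.param)
    ident = np.arange(6)
    # relabeling both graphs consistently leaves the score unchanged
    assert edge_score(ident, ident, g, g) == pytest.approx(
        edge_score(ident, ident, g_perm, g_perm)
    )
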