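"""kNN graph geometry, interaction permutation tests (with a brute-force
enumeration oracle), cellular neighborhoods and distance profiles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import alloatlas as aa
from alloatlas import ConfigurationError
from alloatlas.synth import NEG

from conftest import make_table


# ---------------------------------------------------------------------------
# kNN graph


def test_small_roi_gives_complete_digraph():
    table = make_table([0, 1, 2], [0, 0, 1])
    g = aa.build_knn_graph(table, k=10)
    assert (g.out_degree() == 2).all()  # n-1 < k


def test_collinear_nearest_neighbors():
    table = make_table([0, 1, 3], [0, 0, 0])
    g = aa.build_knn_graph(table, k=1)
    # 0 -> 1, 1 -> 0, 2(at x=3) -> 1
    assert g.neighbors[:, 0].tolist() == [1, 0, 1]
    assert g.distances[:, 0].tolist() == [1.0, 1.0, 2.0]


def test_duplicate_coordinates_tie_break_by_id_is_deterministic():
    table = make_table([0, 0, 0, 5], [0, 0, 0, 0])
    g1 = aa.build_knn_graph(table, k=2)
    g2 = aa.build_knn_graph(table, k=2)
    assert np.array_equal(g1.neighbors, g2.neighbors)
    # equal-distance neighbors appear in row (cell id) order
    assert g1.neighbors[0].tolist() == [1, 2]
    assert g1.neighbors[3].tolist() == [0, 1]


def test_single_cell_roi_skipped_with_warning():
    table = make_table([0], [0])
    with pytest.warns(UserWarning, match="fewer than 2"):
        assert aa.build_knn_graph(table, k=3) is None


def test_neighbors_sorted_by_distance(small_cohort):
    table, _ = small_cohort
    g = next(iter(aa.build_graphs(table.groupby("roi").head(300), k=5).values()))
    d = g.distances
    assert np.all(np.diff(d, axis=1)[~np.isnan(np.diff(d, axis=1))] >= 0)


# ---------------------------------------------------------------------------
# interaction permutation test


def test_single_label_roi_pair_stat_is_k_and_p_one():
    table, labels = make_table(np.arange(6), np.zeros(6), labels="AAAAAA")
    g = aa.build_knn_graph(table, k=3)
    res = aa.test_interactions([g], labels, n_perm=50, seed=0)
    row = res.iloc[0]
    assert row["observed"] == pytest.approx(3.0)  # every neighbor is an A
    assert row["p_attraction"] == 1.0 and row["p_avoidance"] == 1.0
    assert row["call"] == "none"


def _enumeration_oracle(xy, labels, k):
    """Independent brute-force oracle: the full null over distinct labelings,
    statistic computed with plain python loops."""
    labels = list(labels)
    n = len(labels)
    dist = np.hypot(xy[:, None, 0] - xy[None, :, 0], xy[:, None, 1] - xy[None, :, 1])

    def neighbors(i):
        order = sorted((dist[i, j], j) for j in range(n) if j != i)
        return [j for _, j in order[:k]]

    nbrs = [neighbors(i) for i in range(n)]

    def stat(lab, a, b):
        vals = [sum(lab[j] == b for j in nbrs[i]) for i in range(n) if lab[i] == a]
        return np.mean(vals) if vals else np.nan

    pairs = sorted({(a, b) for a in labels for b in labels})
    arrangements = sorted(set(itertools.permutations(labels)))
    out = {}
    for a, b in pairs:
        obs = stat(labels, a, b)
        null = [stat(list(arr), a, b) for arr in arrangements]
        out[(a, b)] = (
            sum(v >= obs - 1e-12 for v in null) / len(null),
            sum(v <= obs + 1e-12 for v in null) / len(null),
        )
    return out


@pytest.mark.parametrize("labels, k", [("AABB", 1), ("AABBC", 2), ("AAABBB", 1)])
def test_exact_p_values_match_enumeration_oracle(labels, k):
    rng = np.random.default_rng(hash(labels) % 2**31)
    xy = rng.uniform(0, 10, (len(labels), 2))
    table, lab = make_table(xy[:, 0], xy[:, 1], labels=labels)
    g = aa.build_knn_graph(table, k=k)
    res = aa.test_interactions([g], lab, exact=True, seed=0)
    oracle = _enumeration_oracle(xy, labels, k)
    for _, row in res.iterrows():
        pa, pv = oracle[(row["from_label"], row["to_label"])]
        assert row["p_attraction"] == pytest.approx(pa, abs=1e-12)
        assert row["p_avoidance"] == pytest.approx(pv, abs=1e-12)


def test_disjoint_tight_clusters_called_avoidance():
    rng = np.random.default_rng(4)
    a = rng.normal([5, 5], 1.0, (40, 2))
    b = rng.normal([80, 80], 1.0, (40, 2))
    xy = np.vstack([a, b])
    table, lab = make_table(xy[:, 0], xy[:, 1], labels="A" * 40 + "B" * 40)
    g = aa.build_knn_graph(table, k=5)
    res = aa.test_interactions([g], lab, n_perm=200, alpha=0.01, seed=1)
    res = res.set_index(["from_label", "to_label"])
    assert res.loc[("A", "B"), "call"] == "avoidance"
    assert res.loc[("A", "A"), "call"] == "attraction"


def test_interaction_calls_never_both_and_p_in_unit_interval(small_cohort, small_assignment):
    table, _ = small_cohort
    _, asg = small_assignment
    graphs = aa.build_graphs(table[table["group"] == "NR"], k=10)
    res = aa.test_interactions(graphs, asg["final"], n_perm=50, seed=2)
    ok = res["p_attraction"].notna()
    assert ((res.loc[ok, "p_attraction"] > 0) & (res.loc[ok, "p_attraction"] <= 1)).all()
    both = (res["p_attraction"] <= 0.01) & (res["p_avoidance"] <= 0.01)
    assert not both.fillna(False).any()


def test_interaction_network_edges_and_strength():
    res = pd.DataFrame(
        {
            "group": ["NR"] * 3,
            "from_label": ["A", "A", "B"],
            "to_label": ["B", "A", "B"],
            "observed": [3.0, 1.0, 2.0],
            "null_mean": [1.0, 1.0, 2.0],
            "null_sd": [0.5, 0.2, 0.0],
            "call": ["attraction", "none", "avoidance"],
        }
    )
    net = aa.interaction_network(res)
    assert len(net) == 2
    assert net.loc[net["from_label"] == "A", "strength"].iloc[0] == pytest.approx(4.0)
    assert net.loc[net["from_label"] == "B", "strength"].iloc[0] == 0.0  # degenerate null


# ---------------------------------------------------------------------------
# neighborhood profiles and cellular neighborhoods


def test_profiles_hand_count_and_normalization():
    # square of 4 A/B/C cells around a center cell: k=4 neighbors {A,A,B,C}
    xy = np.array([[0.0, 0.0], [1, 0], [-1, 0], [0, 1], [0, -1], [50, 50]])
    table, lab = make_table(xy[:, 0], xy[:, 1], labels="XAABC?")
    g = aa.build_knn_graph(table, k=4)
    prof = aa.compute_neighborhood_profiles([g], lab)
    center = prof.iloc[0]
    assert center["A"] == pytest.approx(0.5)
    assert center["B"] == pytest.approx(0.25) and center["C"] == pytest.approx(0.25)
    assert np.allclose(prof.sum(axis=1), 1.0, atol=1e-9)


def test_homogeneous_roi_profiles_are_indicator():
    table, lab = make_table(np.arange(8), np.zeros(8), labels="A" * 8)
    g = aa.build_knn_graph(table, k=3)
    prof = aa.compute_neighborhood_profiles([g], lab)
    assert (prof["A"] == 1.0).all()


def _planted_blocks_cohort(seed=0, cells=4800.0):
    """One ROI at study density, split into two bands whose compositions
    differ in total-variation distance 0.8 (block motifs in tissue are
    near-disjoint mixtures, e.g. a vascular vs a parenchymal region)."""
    cfg = aa.CohortConfig(
        n_patients_per_group={"NR": 1},
        cells_per_roi=cells,
        composition={"NR": {"A": 0.9, "B": 0.1}},
        expression_templates={t: {"M1": NEG} for t in "AB"},
        motif_blocks=[(0.5, {"A": 0.1, "B": 0.9})],
        seed=seed,
    )
    return aa.generate_cohort(cfg)


def test_cn_recovery_of_planted_motif_blocks():
    table, truth = _planted_blocks_cohort(seed=6)
    graphs = aa.build_graphs(table, k=10)
    prof = aa.compute_neighborhood_profiles(graphs, truth.cells["true_label"])
    cn = aa.cluster_neighborhoods(prof, n_cn=2, seed=0)
    ari = adjusted_rand_score(truth.cells.loc[cn.assignment.index, "motif_block"], cn.assignment)
    assert ari >= 0.9


def test_cn_identical_profiles_degenerate_to_one_populated_cluster():
    prof = pd.DataFrame(np.tile([0.5, 0.5], (30, 1)), columns=["A", "B"])
    cn = aa.cluster_neighborhoods(prof, n_cn=3, seed=0)
    assert cn.assignment.nunique() == 1
    assert cn.populated.sum() == 1


def test_cn_determinism_and_too_few_cells():
    rng = np.random.default_rng(0)
    prof = pd.DataFrame(rng.dirichlet([1, 1, 1], 50), columns=list("ABC"))
    a = aa.cluster_neighborhoods(prof, n_cn=4, seed=9).assignment
    b = aa.cluster_neighborhoods(prof, n_cn=4, seed=9).assignment
    pd.testing.assert_series_equal(a, b)
    with pytest.raises(ConfigurationError):
        aa.cluster_neighborhoods(prof.head(3), n_cn=4, seed=0)


def test_cn_proportions_sum_to_one_and_pooling():
    t1 = make_table(np.arange(4), np.zeros(4), patient="p0")
    t2 = make_table(np.arange(4), np.zeros(4), patient="p1", roi="r1")
    table = pd.concat([t1, t2], ignore_index=True)
    assignment = pd.Series([0, 0, 0, 0, 1, 1, 1, 1], index=table.index, name="cn")
    model = aa.spatial.CNModel(n_cn=2, assignment=assignment, centroids=pd.DataFrame(), populated=np.array([True, True]))
    props = aa.cn_proportions(model, table)
    per_patient = props.groupby("patient")["proportion"].sum()
    assert np.allclose(per_patient, 1.0)
    assert props.set_index(["patient", "label"])["proportion"]["p0", "CN0"] == 1.0
    assert props.groupby("label")["proportion"].mean().tolist() == [0.5, 0.5]


# ---------------------------------------------------------------------------
# distance to reference


def test_distance_examples():
    table, lab = make_table([0, 3, 0], [0, 4, 0], labels=["R", "T", "T"])
    prof = aa.distance_to_reference(table, lab, "R")
    got = prof.set_index(prof.index)["distance"]
    assert got.loc[1] == pytest.approx(5.0)  # 3-4-5 triangle
    assert got.loc[2] == 0.0  # coincident with the reference


def test_distance_median_and_missing_reference_roi():
    t1, lab1 = make_table([0, 1, 3, 5], [0] * 4, labels=["R", "T", "T", "T"], roi="r0")
    t2 = make_table([0, 1], [0, 0], roi="r1")
    lab2 = pd.Series(["T", "T"], index=t2.index)
    table = pd.concat([t1, t2], ignore_index=True)
    labels = pd.concat([lab1, lab2], ignore_index=True)
    prof = aa.distance_to_reference(table, labels, "R")
    med = aa.spatial.median_distances(prof, by_group=False).set_index("label")
    assert med.loc["T", "median_distance"] == pytest.approx(3.0)  # {1, 3, 5}
    assert prof["distance"].isna().sum() == 2  # r1 has no reference cells


def test_distance_profile_rigid_motion_invariant():
    rng = np.random.default_rng(3)
    xy = rng.uniform(0, 100, (40, 2))
    labels = ["R"] * 10 + ["T"] * 30
    table, lab = make_table(xy[:, 0], xy[:, 1], labels=labels)
    theta = 0.7
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    xy2 = xy @ rot.T + [20, -7]
    table2, lab2 = make_table(xy2[:, 0], xy2[:, 1], labels=labels)
    d1 = aa.distance_to_reference(table, lab, "R")["distance"].to_numpy()
    d2 = aa.distance_to_reference(table2, lab2, "R")["distance"].to_numpy()
    assert np.allclose(d1, d2)


def test_unknown_reference_label_raises():
    table, lab = make_table([0, 1], [0, 0], labels=["A", "B"])
    with pytest.raises(ConfigurationError):
        aa.distance_to_reference(table, lab, "Endothelial cells")
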