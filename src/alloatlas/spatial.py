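"""Spatial statistics on per-ROI k-nearest-neighbor graphs.

Three statistics are computed on a directed kNN graph (k = 10 by default,
the classic histoCAT-style construction; interaction counts run over
out-edges):

* pairwise interaction tests — for an ordered type pair (A, B), the observed
  statistic is the across-ROI mean of (mean number of B-labeled out-neighbors
  per A-labeled cell). The null is built by permuting labels independently
  within each ROI (stratified), recomputing the across-ROI statistic each
  time. p_attraction = (1 + #{null >= observed}) / (1 + n_perm), p_avoidance
  analogously with <=; a pair is called attraction/avoidance at level alpha
  (0.01 with 1,000 permutations by default). On tiny ROIs the null can be
  enumerated exhaustively over all distinct labelings (``exact=True``).
* cellular neighborhoods — each cell's neighbor-label fraction vector is
  k-means clustered (9 neighborhoods by default) into recurring local
  composition motifs.
* distance profiles — per-cell Euclidean distance to the nearest cell of a
  reference type (endothelial cells in the study) within the same ROI.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans

from ._utils import ConfigurationError, derived_int_seed

_EXACT_CAP = 500_000  # refuse exhaustive enumeration beyond this many labelings


@dataclass
class SpatialGraph:
    """Directed kNN adjacency for one ROI. ``neighbors[i, j]`` is the row
    position of cell i's j-th nearest neighbor (-1 padding when the ROI has
    fewer than k other cells); neighbors are sorted by ascending distance,
    ties broken by cell id."""

    roi: str
    cell_index: pd.Index  # table index of the ROI's cells, in row order
    neighbors: np.ndarray  # (n, k') int positions into cell_index
    distances: np.ndarray  # (n, k') float, NaN padding
    k: int

    @property
    def n_cells(self) -> int:
        return len(self.cell_index)

    def out_degree(self) -> np.ndarray:
        return (self.neighbors >= 0).sum(axis=1)

    def to_edge_list(self) -> pd.DataFrame:
        rows = []
        ids = np.asarray(self.cell_index)
        for i in range(self.n_cells):
            for j, d in zip(self.neighbors[i], self.distances[i]):
                if j >= 0:
                    rows.append((self.roi, ids[i], ids[j], d))
        return pd.DataFrame(rows, columns=["roi", "from_cell", "to_cell", "distance"])


def build_knn_graph(roi_cells: pd.DataFrame, k: int = 10) -> SpatialGraph | None:
    """Directed kNN graph on cell centroids (Euclidean, µm).

    Deterministic tie-breaking: neighbors at equal distance are ordered by
    row position (cell id order). ROIs with fewer than 2 cells are skipped
    with a warning (returns None).
    """
    n = len(roi_cells)
    roi = str(roi_cells["roi"].iloc[0]) if n else ""
    if n < 2:
        warnings.warn(f"ROI {roi!r} has fewer than 2 cells; skipped")
        return None
    xy = roi_cells[["x", "y"]].to_numpy(dtype=float)
    if not np.isfinite(xy).all():
        raise ConfigurationError(f"ROI {roi!r} has non-finite coordinates")
    k_eff = min(k, n - 1)
    tree = cKDTree(xy)
    # query extra candidates so distance ties at the cut boundary can be
    # resolved by cell id; widen until the boundary is tie-free.
    extra = 8
    while True:
        m = min(n, k_eff + 1 + extra)
        dist, idx = tree.query(xy, k=m)
        if m >= n or not np.any(np.isclose(dist[:, k_eff], dist[:, -1])):
            break
        extra *= 2
    nbrs = np.full((n, k_eff), -1, dtype=np.int64)
    nd = np.full((n, k_eff), np.nan)
    for i in range(n):
        cand = [(d, j) for d, j in zip(dist[i], idx[i]) if j != i]
        cand.sort()  # (distance, row position): deterministic tie-break
        take = cand[:k_eff]
        nbrs[i, : len(take)] = [j for _, j in take]
        nd[i, : len(take)] = [d for d, _ in take]
    return SpatialGraph(roi=roi, cell_index=roi_cells.index, neighbors=nbrs, distances=nd, k=k)


def build_graphs(table: pd.DataFrame, k: int = 10) -> dict[str, SpatialGraph]:
    """One kNN graph per ROI of a cell table."""
    graphs = {}
    for roi, cells in table.groupby("roi", sort=True):
        g = build_knn_graph(cells, k=k)
        if g is not None:
            graphs[roi] = g
    return graphs


# ---------------------------------------------------------------------------
# pairwise interaction permutation test


def _roi_pair_matrix(codes: np.ndarray, nbrs: np.ndarray, n_labels: int) -> np.ndarray:
    """(L, L) matrix: M[a, b] = mean over a-labeled cells of the number of
    b-labeled out-neighbors; NaN rows for labels absent from the ROI."""
    n, kk = nbrs.shape
    valid = nbrs >= 0
    nbr_codes = np.where(valid, codes[np.where(valid, nbrs, 0)], -1)
    B = np.zeros((n, n_labels))
    rows = np.repeat(np.arange(n), kk)[valid.ravel()]
    cols = nbr_codes.ravel()[valid.ravel()]
    np.add.at(B, (rows, cols), 1.0)
    counts = np.bincount(codes, minlength=n_labels).astype(float)
    sums = np.zeros((n_labels, n_labels))
    np.add.at(sums, codes, B)
    with np.errstate(invalid="ignore", divide="ignore"):
        M = sums / counts[:, None]
    M[counts == 0] = np.nan
    return M


def _across_roi_mean(mats: list[np.ndarray]) -> np.ndarray:
    stack = np.stack(mats)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        return np.nanmean(stack, axis=0)


def _distinct_labelings(codes: np.ndarray):
    """All distinct arrangements of a label multiset (lexicographic)."""
    seen = set()
    for perm in itertools.permutations(codes.tolist()):
        if perm not in seen:
            seen.add(perm)
            yield np.array(perm, dtype=codes.dtype)


def test_interactions(
    graphs: dict[str, SpatialGraph] | list[SpatialGraph],
    labels: pd.Series,
    group: str | None = None,
    n_perm: int = 1000,
    alpha: float = 0.01,
    seed: int = 0,
    exact: bool = False,
    label_set: list[str] | None = None,
) -> pd.DataFrame:
    """Permutation interaction test for every ordered label pair.

    Returns a tidy frame: group, from_label, to_label, observed, null_mean,
    null_sd, p_attraction, p_avoidance, call, n_perm, alpha. Pairs whose
    from-label occurs in no ROI are reported with missing statistics and
    call "none". With ``exact=True`` the null is the full product of distinct
    within-ROI labelings (only feasible for tiny ROIs) and n_perm is ignored.
    """
    if not (0.0 < alpha < 1.0):
        raise ConfigurationError("alpha must lie in (0, 1)")
    if isinstance(graphs, dict):
        graphs = [graphs[r] for r in sorted(graphs)]
    if label_set is None:
        label_set = sorted(pd.unique(labels.loc[np.concatenate([g.cell_index for g in graphs])]))
    L = len(label_set)
    code_of = {lab: i for i, lab in enumerate(label_set)}
    roi_codes = [labels.loc[g.cell_index].map(code_of).to_numpy(dtype=np.int64) for g in graphs]
    roi_nbrs = [g.neighbors for g in graphs]

    observed = _across_roi_mean([_roi_pair_matrix(c, nb, L) for c, nb in zip(roi_codes, roi_nbrs)])

    if exact:
        per_roi = [list(_distinct_labelings(c)) for c in roi_codes]
        total = int(np.prod([len(p) for p in per_roi]))
        if total > _EXACT_CAP:
            raise ConfigurationError(f"exact enumeration would need {total} labelings (> {_EXACT_CAP})")
        null_iter = (
            _across_roi_mean([_roi_pair_matrix(c, nb, L) for c, nb in zip(combo, roi_nbrs)])
            for combo in itertools.product(*per_roi)
        )
        n_null = total
        plus_one = 0  # the observed labeling is part of the enumeration
    else:
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(211,)))

        def _null_gen():
            for _ in range(n_perm):
                yield _across_roi_mean(
                    [_roi_pair_matrix(rng.permutation(c), nb, L) for c, nb in zip(roi_codes, roi_nbrs)]
                )

        null_iter = _null_gen()
        n_null = n_perm
        plus_one = 1

    n_ge = np.zeros((L, L))
    n_le = np.zeros((L, L))
    s1 = np.zeros((L, L))
    s2 = np.zeros((L, L))
    for M in null_iter:
        with np.errstate(invalid="ignore"):
            n_ge += (M >= observed - 1e-12).astype(float)
            n_le += (M <= observed + 1e-12).astype(float)
        s1 += np.nan_to_num(M)
        s2 += np.nan_to_num(M) ** 2
    p_att = (plus_one + n_ge) / (plus_one + n_null)
    p_avo = (plus_one + n_le) / (plus_one + n_null)
    null_mean = s1 / n_null
    null_var = np.maximum(s2 / n_null - null_mean**2, 0.0)
    null_sd = np.sqrt(null_var)

    rows = []
    for a in range(L):
        for b in range(L):
            if np.isnan(observed[a, b]):
                rows.append((group, label_set[a], label_set[b], np.nan, np.nan, np.nan, np.nan, np.nan, "none"))
                continue
            pa, pv = p_att[a, b], p_avo[a, b]
            call = "attraction" if pa <= alpha else ("avoidance" if pv <= alpha else "none")
            rows.append((group, label_set[a], label_set[b], observed[a, b], null_mean[a, b], null_sd[a, b], pa, pv, call))
    out = pd.DataFrame(
        rows,
        columns=["group", "from_label", "to_label", "observed", "null_mean", "null_sd", "p_attraction", "p_avoidance", "call"],
    )
    out["n_perm"] = n_null
    out["alpha"] = alpha
    return out


def test_interactions_by_group(
    graphs: dict[str, SpatialGraph],
    labels: pd.Series,
    table: pd.DataFrame,
    n_perm: int = 1000,
    alpha: float = 0.01,
    seed: int = 0,
) -> pd.DataFrame:
    """Run the interaction test separately on each clinical subset."""
    roi_group = table.drop_duplicates("roi").set_index("roi")["group"]
    results = []
    for gi, group in enumerate(sorted(roi_group.unique())):
        sub = {r: g for r, g in graphs.items() if roi_group[r] == group}
        if not sub:
            continue
        results.append(
            test_interactions(sub, labels, group=group, n_perm=n_perm, alpha=alpha, seed=derived_int_seed(seed, 7, gi))
        )
    return pd.concat(results, ignore_index=True)


def interaction_network(results: pd.DataFrame) -> pd.DataFrame:
    """Edge list of significant interactions; strength is the standardized
    deviation of the observed statistic from its permutation null
    (|observed - null mean| / null sd; 0 for a degenerate null)."""
    sig = results[results["call"] != "none"].copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        strength = np.abs(sig["observed"] - sig["null_mean"]) / sig["null_sd"]
    sig["strength"] = np.where((sig["null_sd"] > 0), strength, 0.0)
    cols = ["group", "from_label", "to_label", "call", "strength"]
    return sig[cols].reset_index(drop=True)


# ---------------------------------------------------------------------------
# cellular neighborhoods


def compute_neighborhood_profiles(
    graphs: dict[str, SpatialGraph] | list[SpatialGraph],
    labels: pd.Series,
    label_set: list[str] | None = None,
) -> pd.DataFrame:
    """Per-cell fraction of out-neighbors bearing each label (rows sum to 1).

    Fractions (not counts) keep boundary cells with degree < k comparable.
    """
    if isinstance(graphs, dict):
        graphs = [graphs[r] for r in sorted(graphs)]
    if label_set is None:
        label_set = sorted(pd.unique(labels.loc[np.concatenate([g.cell_index for g in graphs])]))
    code_of = {lab: i for i, lab in enumerate(label_set)}
    blocks = []
    for g in graphs:
        codes = labels.loc[g.cell_index].map(code_of).to_numpy(dtype=np.int64)
        valid = g.neighbors >= 0
        nbr_codes = np.where(valid, codes[np.where(valid, g.neighbors, 0)], -1)
        B = np.zeros((g.n_cells, len(label_set)))
        rows = np.repeat(np.arange(g.n_cells), g.neighbors.shape[1])[valid.ravel()]
        np.add.at(B, (rows, nbr_codes.ravel()[valid.ravel()]), 1.0)
        deg = valid.sum(axis=1).astype(float)
        blocks.append(pd.DataFrame(B / deg[:, None], index=g.cell_index, columns=label_set))
    return pd.concat(blocks)


class NeighborhoodKMeans(ClusterMixin, BaseEstimator):
    """K-means over neighbor-composition profiles (k-means++ init, best of 10
    restarts by inertia, fixed seed) defining the cellular neighborhoods."""

    def __init__(self, n_cn: int = 9, seed: int = 0, n_init: int = 10):
        self.n_cn = n_cn
        self.seed = seed
        self.n_init = n_init

    def fit(self, X: pd.DataFrame, y=None):
        if len(X) < self.n_cn:
            raise ConfigurationError(f"need at least n_cn={self.n_cn} cells, got {len(X)}")
        km = KMeans(n_clusters=self.n_cn, n_init=self.n_init, random_state=self.seed)
        self.labels_ = km.fit_predict(np.asarray(X, dtype=float))
        self.centroids_ = pd.DataFrame(km.cluster_centers_, columns=X.columns)
        self.centroids_.index.name = "cn"
        self.populated_ = np.isin(np.arange(self.n_cn), self.labels_)
        self.cell_index_ = X.index
        return self

    def assignment(self) -> pd.Series:
        return pd.Series(self.labels_, index=self.cell_index_, name="cn")


@dataclass
class CNModel:
    n_cn: int
    assignment: pd.Series  # cell -> CN id
    centroids: pd.DataFrame  # CN x label composition
    populated: np.ndarray  # CN ids actually used
    names: dict[int, str] | None = None


def cluster_neighborhoods(profiles: pd.DataFrame, n_cn: int = 9, seed: int = 0) -> CNModel:
    """Cluster neighbor profiles into n_cn cellular neighborhoods."""
    est = NeighborhoodKMeans(n_cn=n_cn, seed=seed).fit(profiles)
    return CNModel(n_cn=n_cn, assignment=est.assignment(), centroids=est.centroids_, populated=est.populated_)


def cn_proportions(model: CNModel, table: pd.DataFrame) -> pd.DataFrame:
    """Per-patient cellular-neighborhood composition (sums to 1)."""
    df = pd.DataFrame(
        {
            "patient": table.loc[model.assignment.index, "patient"].to_numpy(),
            "group": table.loc[model.assignment.index, "group"].to_numpy(),
            "cn": model.assignment.to_numpy(),
        }
    )
    counts = df.groupby(["patient", "cn"]).size().unstack(fill_value=0).reindex(columns=range(model.n_cn), fill_value=0)
    props = counts.div(counts.sum(axis=1), axis=0)
    patients = df.drop_duplicates("patient").set_index("patient")["group"]
    tidy = props.reset_index().melt(id_vars="patient", var_name="cn", value_name="proportion")
    tidy["group"] = tidy["patient"].map(patients)
    tidy["label"] = tidy["cn"].map(lambda c: f"CN{c}")
    return tidy[["patient", "group", "label", "proportion"]].sort_values(
        ["patient", "label"], kind="stable", ignore_index=True
    )


# ---------------------------------------------------------------------------
# distance to a reference cell type


def distance_to_reference(
    table: pd.DataFrame,
    labels: pd.Series,
    reference_label: str,
) -> pd.DataFrame:
    """Per-cell Euclidean distance (µm) to the nearest reference-type cell in
    the same ROI; ROIs lacking reference cells contribute missing values.

    Returns a frame indexed like the non-reference cells with columns
    group, label, distance.
    """
    if reference_label not in set(labels.unique()):
        raise ConfigurationError(f"reference label {reference_label!r} not present in the label set")
    out = []
    for roi, cells in table.groupby("roi", sort=True):
        lab = labels.loc[cells.index]
        is_ref = (lab == reference_label).to_numpy()
        others = cells.index[~is_ref]
        if len(others) == 0:
            continue
        if is_ref.sum() == 0:
            dist = np.full(len(others), np.nan)
        else:
            tree = cKDTree(cells.loc[cells.index[is_ref], ["x", "y"]].to_numpy(dtype=float))
            dist, _ = tree.query(cells.loc[others, ["x", "y"]].to_numpy(dtype=float), k=1)
        out.append(
            pd.DataFrame(
                {"group": cells.loc[others, "group"].to_numpy(), "label": lab.loc[others].to_numpy(), "distance": dist},
                index=others,
            )
        )
    return pd.concat(out)


def median_distances(profile: pd.DataFrame, by_group: bool = True) -> pd.DataFrame:
    """Per-label (optionally per-group) median distance to the reference type."""
    keys = ["group", "label"] if by_group else ["label"]
    return profile.groupby(keys, dropna=False)["distance"].median().reset_index(name="median_distance")
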