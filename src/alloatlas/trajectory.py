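"""Per-metacluster trajectory orientation and pseudotime.

The procedure mirrors pseudotemporal analysis of a single cell compartment:

1. embed the compartment's standardized expression in 2-D (principal
   components by default: deterministic, adequate for ordering);
2. coarse k-means clustering (k = 2, except k = 5 for the CD8 T-cell
   compartment) and orientation: the coarse cluster with the highest
   fraction of cells from NR samples is the initial (root) cluster, on the
   premise that non-rejecting tissue carries the least differentiated state;
3. lineages: instead of iterative simultaneous principal curves, a minimum
   spanning tree is built over the coarse-cluster centroids and rooted at
   the initial cluster; each root-to-leaf path is one lineage. Pseudotime is
   the arc-length position of a cell's orthogonal projection onto the
   piecewise-linear path of its nearest lineage, so the root centroid sits
   at pseudotime 0 and branching order is preserved. This keeps the
   scientific content (orientation + branching) of principal-curve methods
   with far less machinery; it does not reproduce their smoothed curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from ._utils import ConfigurationError, DataError, marker_columns, derived_int_seed


@dataclass
class TrajectoryResult:
    embedding: np.ndarray  # (n, 2)
    coarse_clusters: np.ndarray  # (n,) int
    initial_cluster: int
    lineages: list[list[int]]  # ordered coarse-cluster ids, root first
    lineage_paths: list[np.ndarray]  # ordered centroid coordinates per lineage
    cell_lineage: np.ndarray  # (n,) lineage index per cell
    pseudotime: np.ndarray  # (n,) >= 0, root centroid at 0
    index: pd.Index

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dim1": self.embedding[:, 0],
                "dim2": self.embedding[:, 1],
                "coarse_cluster": self.coarse_clusters,
                "lineage": self.cell_lineage,
                "pseudotime": self.pseudotime,
            },
            index=self.index,
        )


def embed_metacluster(cells: pd.DataFrame, seed: int = 0) -> np.ndarray:
    """2-D embedding of one compartment's standardized expression.

    Principal components with sklearn's deterministic sign convention; any
    manifold embedding would do for ordering purposes.
    """
    if len(cells) < 10:
        raise DataError(f"need at least 10 cells to embed, got {len(cells)}")
    X = cells[marker_columns(cells)].to_numpy(dtype=float)
    n_comp = min(2, X.shape[1])
    emb = PCA(n_components=n_comp, random_state=seed).fit_transform(X)
    if n_comp == 1:
        emb = np.column_stack([emb[:, 0], np.zeros(len(emb))])
    return emb


def orient_trajectory(
    embedding: np.ndarray,
    groups: pd.Series | np.ndarray,
    coarse_k: int = 2,
    seed: int = 0,
    nr_label: str = "NR",
) -> tuple[int, np.ndarray]:
    """Coarse k-means and the orientation rule: the cluster with the highest
    proportion of NR cells is the initial cluster (ties -> lowest id).

    Returns (initial cluster id, per-cell coarse cluster ids).
    """
    if coarse_k < 2:
        raise ConfigurationError("coarse_k must be >= 2")
    groups = np.asarray(groups)
    if not (groups == nr_label).any():
        raise DataError(f"orientation undefined: no {nr_label!r} cells present")
    km = KMeans(n_clusters=coarse_k, n_init=10, random_state=seed)
    clusters = km.fit_predict(np.asarray(embedding, dtype=float))
    fractions = np.array(
        [(groups[clusters == c] == nr_label).mean() if (clusters == c).any() else -1.0 for c in range(coarse_k)]
    )
    return int(np.argmax(fractions)), clusters  # argmax takes the lowest id on ties


def _mst_paths(centroids: np.ndarray, root: int) -> list[list[int]]:
    """Root-to-leaf paths of the Euclidean MST over cluster centroids."""
    k = len(centroids)
    if k == 1:
        return [[root]]
    dense = cdist(centroids, centroids)
    mst = minimum_spanning_tree(dense).toarray()
    adj = [[] for _ in range(k)]
    for i in range(k):
        for j in range(k):
            if mst[i, j] > 0 or mst[j, i] > 0:
                if j not in adj[i]:
                    adj[i].append(j)
                if i not in adj[j]:
                    adj[j].append(i)
    paths: list[list[int]] = []

    def walk(node: int, path: list[int], seen: set[int]) -> None:
        children = [c for c in adj[node] if c not in seen]
        if not children:
            paths.append(path.copy())
            return
        for c in sorted(children):
            walk(c, path + [c], seen | {c})

    walk(root, [root], {root})
    return paths


def _project_onto_polyline(points: np.ndarray, path: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Arc-length position and distance of each point's nearest orthogonal
    projection onto a piecewise-linear path."""
    if len(path) == 1:
        d = np.linalg.norm(points - path[0], axis=1)
        return np.zeros(len(points)), d
    seg_start = path[:-1]
    seg_vec = path[1:] - seg_start
    seg_len = np.linalg.norm(seg_vec, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    best_arc = np.zeros(len(points))
    best_dist = np.full(len(points), np.inf)
    for s in range(len(seg_vec)):
        v = seg_vec[s]
        L2 = max(seg_len[s] ** 2, 1e-300)
        t = np.clip(((points - seg_start[s]) @ v) / L2, 0.0, 1.0)
        proj = seg_start[s] + t[:, None] * v
        dist = np.linalg.norm(points - proj, axis=1)
        better = dist < best_dist
        best_dist[better] = dist[better]
        best_arc[better] = cum[s] + t[better] * seg_len[s]
    return best_arc, best_dist


def infer_lineages_and_pseudotime(
    embedding: np.ndarray,
    coarse_clusters: np.ndarray,
    initial_cluster: int,
    index: pd.Index | None = None,
) -> TrajectoryResult:
    """Lineages = root-to-leaf MST paths over coarse-cluster centroids;
    pseudotime = arc-length of each cell's projection onto its nearest
    lineage path. A single coarse cluster degenerates to distance from the
    centroid along the first principal axis."""
    embedding = np.asarray(embedding, dtype=float)
    coarse_clusters = np.asarray(coarse_clusters)
    ids = np.unique(coarse_clusters)
    centroids = np.vstack([embedding[coarse_clusters == c].mean(axis=0) for c in ids])
    pos_of = {c: i for i, c in enumerate(ids)}
    root = pos_of[initial_cluster]

    if len(ids) == 1:
        centered = embedding - centroids[0]
        axis = PCA(n_components=1).fit(centered).components_[0]
        pt = np.abs(centered @ axis)
        lineages = [[int(initial_cluster)]]
        result = TrajectoryResult(
            embedding=embedding,
            coarse_clusters=coarse_clusters,
            initial_cluster=int(initial_cluster),
            lineages=lineages,
            lineage_paths=[centroids.copy()],
            cell_lineage=np.zeros(len(embedding), dtype=int),
            pseudotime=pt,
            index=index if index is not None else pd.RangeIndex(len(embedding)),
        )
        return result

    pos_paths = _mst_paths(centroids, root)
    lineages = [[int(ids[p]) for p in path] for path in pos_paths]
    paths_xy = [centroids[path] for path in pos_paths]
    arcs = np.zeros((len(paths_xy), len(embedding)))
    dists = np.zeros((len(paths_xy), len(embedding)))
    for li, path in enumerate(paths_xy):
        arcs[li], dists[li] = _project_onto_polyline(embedding, path)
    cell_lineage = np.argmin(dists, axis=0)
    pseudotime = arcs[cell_lineage, np.arange(len(embedding))]
    return TrajectoryResult(
        embedding=embedding,
        coarse_clusters=coarse_clusters,
        initial_cluster=int(initial_cluster),
        lineages=lineages,
        lineage_paths=paths_xy,
        cell_lineage=cell_lineage,
        pseudotime=pseudotime,
        index=index if index is not None else pd.RangeIndex(len(embedding)),
    )


def pseudotime_density_by_group(
    result: TrajectoryResult,
    groups: pd.Series | np.ndarray,
    n_bins: int = 30,
    min_cells: int = 5,
) -> pd.DataFrame:
    """Per-group histogram over pseudotime (masses sum to 1 per group);
    groups with fewer than `min_cells` cells are flagged."""
    groups = np.asarray(groups)
    lo, hi = float(result.pseudotime.min()), float(result.pseudotime.max())
    if hi <= lo:
        hi = lo + 1.0
    edges = np.linspace(lo, hi, n_bins + 1)
    rows = []
    for g in sorted(pd.unique(groups)):
        pts = result.pseudotime[groups == g]
        hist, _ = np.histogram(pts, bins=edges)
        mass = hist / hist.sum() if hist.sum() else np.zeros(n_bins)
        flagged = len(pts) < min_cells
        for b in range(n_bins):
            rows.append((g, 0.5 * (edges[b] + edges[b + 1]), mass[b], len(pts), flagged))
    return pd.DataFrame(rows, columns=["group", "pseudotime", "mass", "n_cells", "flagged"])


class TrajectoryModel(BaseEstimator):
    """End-to-end trajectory estimator for one compartment: embed, orient by
    the NR-fraction rule, infer MST lineages and pseudotime."""

    def __init__(self, coarse_k: int = 2, seed: int = 0, nr_label: str = "NR"):
        self.coarse_k = coarse_k
        self.seed = seed
        self.nr_label = nr_label

    def fit(self, cells: pd.DataFrame, groups: pd.Series):
        emb = embed_metacluster(cells, seed=derived_int_seed(self.seed, 3))
        initial, clusters = orient_trajectory(
            emb, groups, coarse_k=self.coarse_k, seed=derived_int_seed(self.seed, 5), nr_label=self.nr_label
        )
        self.result_ = infer_lineages_and_pseudotime(emb, clusters, initial, index=cells.index)
        self.initial_cluster_ = initial
        self.pseudotime_ = self.result_.pseudotime
        return self
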