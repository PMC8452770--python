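"""Single-cell KNN graph, clustering, cluster-graph aggregation and root choice.

The cluster graph built here is the substrate for every random walk in the
package: nodes are cell clusters, the symmetric weight matrix ``W`` aggregates
single-cell affinities between clusters, and the diagonal degree matrix ``D``
collects weighted node degrees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import networkx as nx
import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import KMeans
from sklearn.neighbors import NearestNeighbors

from .errors import DataError, GraphError, LookupFailure, ParameterError

_METRICS = ("euclidean", "cosine")


@dataclass
class FeatureMatrix:
    """A cells x features numeric matrix with ordered identifiers."""

    values: np.ndarray | sp.spmatrix
    cell_ids: np.ndarray
    feature_ids: np.ndarray

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.feature_ids = np.asarray(self.feature_ids, dtype=object)
        n, p = self.values.shape
        if n < 2:
            raise DataError(f"need at least 2 cells, got {n}")
        if p < 1:
            raise DataError(f"need at least 1 feature, got {p}")
        if len(self.cell_ids) != n or len(self.feature_ids) != p:
            raise DataError("identifier lengths do not match matrix shape")
        dense = self.values.data if sp.issparse(self.values) else self.values
        if not np.all(np.isfinite(dense)):
            raise DataError("feature matrix contains non-finite entries")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        return self.values.toarray() if sp.issparse(self.values) else np.asarray(self.values)

    @classmethod
    def from_array(cls, values, cell_ids=None, feature_ids=None) -> "FeatureMatrix":
        values = values if sp.issparse(values) else np.asarray(values, dtype=float)
        n, p = values.shape
        if cell_ids is None:
            cell_ids = np.array([f"cell_{i}" for i in range(n)], dtype=object)
        if feature_ids is None:
            feature_ids = np.array([f"feature_{j}" for j in range(p)], dtype=object)
        return cls(values, np.asarray(cell_ids, dtype=object), np.asarray(feature_ids, dtype=object))


@dataclass
class SingleCellKNNGraph:
    """Directed K-neighbour lists plus the symmetrised affinity matrix."""

    neighbor_indices: np.ndarray  # (n_cells, K) int
    neighbor_weights: np.ndarray  # (n_cells, K) float, >= 0
    adjacency: sp.csr_matrix      # symmetric union (max) of directed affinities
    K: int
    metric: str

    @property
    def n_cells(self) -> int:
        return self.adjacency.shape[0]

    def components(self) -> tuple[int, np.ndarray]:
        n_comp, labels = connected_components(self.adjacency, directed=False)
        return n_comp, labels


@dataclass
class ClusterAssignment:
    """One contiguous cluster id per cell."""

    labels: np.ndarray
    n_clusters: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        uniq = np.unique(self.labels)
        if self.n_clusters == 0:
            self.n_clusters = len(uniq)
        if not np.array_equal(uniq, np.arange(self.n_clusters)):
            raise DataError("cluster ids must be contiguous 0..n_clusters-1 and non-empty")

    def membership(self) -> sp.csr_matrix:
        """One-hot cells x clusters indicator matrix."""
        n = len(self.labels)
        return sp.csr_matrix(
            (np.ones(n), (np.arange(n), self.labels)), shape=(n, self.n_clusters)
        )


@dataclass
class ClusterGraph:
    """Weighted undirected graph over cell clusters (W symmetric, zero diagonal)."""

    W: np.ndarray

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise GraphError("W must be square")
        if np.any(W < 0):
            raise GraphError("edge weights must be nonnegative")
        if not np.allclose(W, W.T):
            raise GraphError("W must be symmetric")
        np.fill_diagonal(W, 0.0)
        self.W = W

    @property
    def n_nodes(self) -> int:
        return self.W.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return self.W.sum(axis=1)

    def components(self) -> tuple[int, np.ndarray]:
        n_comp, labels = connected_components(sp.csr_matrix(self.W), directed=False)
        return n_comp, labels

    def edges(self) -> list[tuple[int, int, float]]:
        iu, ju = np.triu_indices(self.n_nodes, k=1)
        mask = self.W[iu, ju] > 0
        return list(zip(iu[mask].tolist(), ju[mask].tolist(), self.W[iu, ju][mask].tolist()))

    def subgraph(self, nodes: np.ndarray) -> "ClusterGraph":
        nodes = np.asarray(nodes, dtype=int)
        return ClusterGraph(self.W[np.ix_(nodes, nodes)])

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_weighted_edges_from(self.edges())
        return g


@dataclass
class RootSpec:
    """How the user designates the starting state."""

    mode: str  # cell_index / group_label / cluster_id
    value: int | str

    def __post_init__(self) -> None:
        if self.mode not in ("cell_index", "group_label", "cluster_id"):
            raise ParameterError(f"unknown root mode {self.mode!r}")


def build_knn_graph(X: FeatureMatrix, K: int, metric: str = "euclidean") -> SingleCellKNNGraph:
    """Exact K-nearest-neighbour graph with a locally adaptive Gaussian kernel.

    Distances are converted to affinities via ``w = exp(-d^2 / sigma_i^2)``
    where ``sigma_i`` is the mean distance from cell ``i`` to its K
    neighbours; the directed graph is then symmetrised by taking, for each
    unordered pair, the maximum of the two directed weights (union rule).
    """
    n = X.n_cells
    if K <= 0 or K >= n:
        raise ParameterError(f"K must satisfy 0 < K < n_cells, got K={K}, n={n}")
    if metric not in _METRICS:
        raise ParameterError(f"metric must be one of {_METRICS}, got {metric!r}")
    V = X.dense()
    nn = NearestNeighbors(n_neighbors=K + 1, metric=metric, algorithm="brute")
    nn.fit(V)
    dist, idx = nn.kneighbors(V)
    # drop the self match per row (may not be first under distance ties)
    keep_idx = np.empty((n, K), dtype=int)
    keep_dist = np.empty((n, K))
    for i in range(n):
        self_pos = np.flatnonzero(idx[i] == i)
        drop = self_pos[0] if len(self_pos) else K  # duplicates: drop last
        sel = np.concatenate([np.arange(drop), np.arange(drop + 1, K + 1)])
        keep_idx[i] = idx[i, sel]
        keep_dist[i] = dist[i, sel]
    idx, dist = keep_idx, keep_dist
    sigma = dist.mean(axis=1)
    sigma[sigma == 0] = 1.0  # duplicated points: unit affinity
    w = np.exp(-(dist ** 2) / sigma[:, None] ** 2)
    rows = np.repeat(np.arange(n), K)
    directed = sp.csr_matrix((w.ravel(), (rows, idx.ravel())), shape=(n, n))
    adjacency = directed.maximum(directed.T).tocsr()
    adjacency.setdiag(0.0)
    adjacency.eliminate_zeros()
    return SingleCellKNNGraph(idx, w, adjacency, K, metric)


def cluster_cells(
    g: SingleCellKNNGraph | None = None,
    X: FeatureMatrix | None = None,
    method: str = "community_detection",
    resolution: float = 1.0,
    k: int = 8,
    seed: int = 42,
) -> ClusterAssignment:
    """Group cells by Leiden community detection on the KNN graph or by K-means.

    Labels are relabelled to be contiguous in order of first appearance, and
    both backends are deterministic for a fixed ``seed``.
    """
    if method == "community_detection":
        if g is None:
            raise ParameterError("community detection requires the KNN graph")
        if g.n_cells == 0:
            raise DataError("empty graph")
        if resolution <= 0:
            raise ParameterError(f"resolution must be positive, got {resolution}")
        A = sp.triu(g.adjacency.tocoo(), k=0)
        edges = list(zip(A.row.tolist(), A.col.tolist()))
        graph = ig.Graph(n=g.n_cells, edges=edges)
        part = leidenalg.find_partition(
            graph,
            leidenalg.RBConfigurationVertexPartition,
            weights=A.data.tolist(),
            resolution_parameter=resolution,
            seed=seed,
            n_iterations=2,
        )
        labels = np.asarray(part.membership, dtype=int)
    elif method == "kmeans":
        if X is None:
            raise ParameterError("kmeans requires the feature matrix")
        if k < 1:
            raise ParameterError(f"k must be >= 1, got {k}")
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        labels = km.fit_predict(X.dense())
    else:
        raise ParameterError(f"unknown clustering method {method!r}")
    # contiguous relabel by order of first appearance
    _, first = np.unique(labels, return_index=True)
    order = labels[np.sort(first)]
    remap = {old: new for new, old in enumerate(order)}
    labels = np.array([remap[v] for v in labels], dtype=int)
    return ClusterAssignment(labels)


def build_cluster_graph(
    g: SingleCellKNNGraph, a: ClusterAssignment, aggregation: str = "sum"
) -> ClusterGraph:
    """Aggregate inter-cluster single-cell edge weights into the cluster graph.

    ``sum`` (default) adds up all single-cell affinities between two clusters;
    ``mean`` divides that sum by the number of contributing single-cell edges.
    """
    if len(a.labels) != g.n_cells:
        raise DataError("cluster assignment does not cover all cells of the graph")
    M = a.membership()
    Wc = np.asarray((M.T @ g.adjacency @ M).todense(), dtype=float)
    if aggregation == "mean":
        counts = np.asarray((M.T @ (g.adjacency > 0).astype(float) @ M).todense())
        with np.errstate(invalid="ignore", divide="ignore"):
            Wc = np.where(counts > 0, Wc / np.maximum(counts, 1), 0.0)
    elif aggregation != "sum":
        raise ParameterError(f"unknown aggregation {aggregation!r}")
    Wc = 0.5 * (Wc + Wc.T)
    np.fill_diagonal(Wc, 0.0)
    return ClusterGraph(Wc)


def _leafness_rank(cg: ClusterGraph, candidates: list[int]) -> int:
    """Break ties between root candidates: prefer leaf-like nodes.

    Ranks by high degree-count (out-degree on the undirected view), then low
    betweenness, then low closeness centrality, then lowest cluster id.
    """
    G = cg.to_networkx()
    btw = nx.betweenness_centrality(G, normalized=False)
    clo = nx.closeness_centrality(G)
    deg = dict(G.degree())
    ranked = sorted(candidates, key=lambda q: (-deg[q], btw[q], clo[q], q))
    return ranked[0]


def select_root(
    cg: ClusterGraph,
    a: ClusterAssignment,
    spec: RootSpec,
    annotations: np.ndarray | None = None,
) -> int:
    """Resolve a root specification to a single cluster id, deterministically."""
    if spec.mode == "cluster_id":
        cid = int(spec.value)
        if not (0 <= cid < cg.n_nodes):
            raise LookupFailure(f"cluster id {cid} out of range")
        return cid
    if spec.mode == "cell_index":
        ci = int(spec.value)
        if not (0 <= ci < len(a.labels)):
            raise LookupFailure(f"cell index {ci} out of range")
        return int(a.labels[ci])
    # group_label: cluster holding the largest fraction of the labelled group
    if annotations is None:
        raise ParameterError("group_label root mode requires per-cell annotations")
    annotations = np.asarray(annotations, dtype=object)
    mask = annotations == spec.value
    if not mask.any():
        raise LookupFailure(f"label {spec.value!r} absent from annotations")
    fractions = np.zeros(a.n_clusters)
    for c in range(a.n_clusters):
        members = a.labels == c
        fractions[c] = mask[members].mean() if members.any() else 0.0
    best = fractions.max()
    candidates = [int(c) for c in np.flatnonzero(np.isclose(fractions, best))]
    if len(candidates) == 1:
        return candidates[0]
    return _leafness_rank(cg, candidates)
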