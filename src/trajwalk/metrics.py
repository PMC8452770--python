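"""Trajectory scoring: spectral distance, edit distance, F1 scores, composite.

An inferred trajectory is compared with its reference at the level of
cell-type (branch) labels: inferred clusters are mapped to types by majority
vote, the type-level graphs are compared globally (Ipsen-Mikhailov spectral
distance) and locally (graph edit distance, F1 over type edges), pseudotime
quality is the Pearson correlation against true times, and terminal-fate
prediction is an F1 score.  The composite converts every metric to a
percentage and averages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import networkx as nx
import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.stats import pearsonr

from .errors import CapacityError, DataError, ParameterError

# ---------------------------------------------------------------------------
# Ipsen-Mikhailov spectral distance


def _omega(G: nx.Graph, n_pad: int) -> np.ndarray:
    """Vibrational frequencies sqrt(lambda) of the padded Laplacian spectrum."""
    A = np.zeros((n_pad, n_pad))
    nodes = list(G.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    for u, v in G.edges:
        if u == v:
            continue
        A[idx[u], idx[v]] = A[idx[v], idx[u]] = 1.0
    L = np.diag(A.sum(1)) - A
    lam = np.linalg.eigvalsh(L)
    lam = np.clip(lam, 0.0, None)
    return np.sqrt(lam[1:])  # drop one trivial zero mode


def _im_given_gamma(w1: np.ndarray, w2: np.ndarray, gamma: float) -> float:
    K1 = 1.0 / (np.pi / 2 + np.arctan(w1 / gamma)).sum()
    K2 = 1.0 / (np.pi / 2 + np.arctan(w2 / gamma)).sum()

    def rho_diff(w):
        r1 = K1 * (gamma / ((w - w1) ** 2 + gamma ** 2)).sum()
        r2 = K2 * (gamma / ((w - w2) ** 2 + gamma ** 2)).sum()
        return (r1 - r2) ** 2

    hi = max(w1.max(initial=0.0), w2.max(initial=0.0)) + 20 * gamma
    val, _ = quad(rho_diff, 0.0, hi, limit=200)
    return float(np.sqrt(val))


@lru_cache(maxsize=64)
def _calibrated_gamma(n: int) -> float:
    """Lorentzian width making distance(empty_n, complete_n) exactly 1."""
    if n < 2:
        return 0.4
    w_empty = np.zeros(n - 1)
    w_complete = np.sqrt(np.full(n - 1, float(n)))

    def f(g):
        return _im_given_gamma(w_empty, w_complete, g) - 1.0

    return float(brentq(f, 0.01, 5.0, xtol=1e-10))


def im_distance(G1: nx.Graph, G2: nx.Graph) -> float:
    """Ipsen-Mikhailov distance between the undirected views of two graphs.

    The Lorentzian-smoothed Laplacian spectral densities are compared in L2;
    the width gamma is calibrated per node count so the empty and complete
    graphs are at distance 1.  Graphs of unequal size are padded with
    isolated nodes.
    """
    G1u, G2u = G1.to_undirected(), G2.to_undirected()
    n = max(G1u.number_of_nodes(), G2u.number_of_nodes(), 2)
    gamma = _calibrated_gamma(n)
    d = _im_given_gamma(_omega(G1u, n), _omega(G2u, n), gamma)
    return float(min(max(d, 0.0), 1.0))


# ---------------------------------------------------------------------------
# Graph edit distance


def graph_edit_distance(
    G_TI: nx.Graph,
    G_REF: nx.Graph,
    labeled: bool = True,
    approximate: bool = False,
    size_limit: int = 12,
) -> int:
    """Minimal unit-cost node/edge insertions + deletions turning G_TI into G_REF.

    Node identity (its type label) is respected when ``labeled``; substituting
    one label for another costs a deletion plus an insertion.  Exact search is
    used up to ``size_limit`` nodes; beyond that an announced approximation
    (first improvement of the optimizer) must be requested explicitly.
    """
    n = max(G_TI.number_of_nodes(), G_REF.number_of_nodes())
    big = n > size_limit

    def nsubst(a, b):
        if not labeled:
            return 0.0
        return 0.0 if a.get("label", a) == b.get("label", b) else 2.0

    kwargs = dict(
        node_subst_cost=lambda a, b: nsubst(a, b),
        node_del_cost=lambda a: 1.0,
        node_ins_cost=lambda a: 1.0,
        edge_subst_cost=lambda a, b: 0.0,
        edge_del_cost=lambda a: 1.0,
        edge_ins_cost=lambda a: 1.0,
    )
    if big:
        if not approximate:
            raise CapacityError(
                f"{n} nodes exceeds the exact-search budget ({size_limit}); "
                "pass approximate=True"
            )
        dist = next(nx.optimize_graph_edit_distance(G_TI, G_REF, **kwargs))
    else:
        dist = nx.graph_edit_distance(G_TI, G_REF, **kwargs)
    return int(round(dist))


def _labeled_graph(nodes, edges) -> nx.Graph:
    g = nx.Graph()
    for v in nodes:
        g.add_node(v, label=v)
    g.add_edges_from((tuple(e) for e in edges))
    return g


# ---------------------------------------------------------------------------
# F1 scores, correlation, composite


def f1_branch(inferred_edges: set, reference_edges: set) -> float:
    """F1 over type-level edges (harmonic mean of precision and recall)."""
    inf = {frozenset(e) for e in inferred_edges}
    ref = {frozenset(e) for e in reference_edges}
    if not inf and not ref:
        return 1.0
    tp = len(inf & ref)
    fp = len(inf - ref)
    fn = len(ref - inf)
    if tp == 0:
        return 0.0
    return tp / (tp + 0.5 * (fp + fn))


def temporal_correlation(t_inferred: np.ndarray, t_true: np.ndarray) -> float:
    """Pearson correlation between inferred pseudotime and true sampling time."""
    x = np.asarray(t_inferred, dtype=float)
    y = np.asarray(t_true, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise DataError("need equal-length vectors with at least 3 cells")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DataError("correlation undefined for a constant vector")
    return float(pearsonr(x, y)[0])


def f1_fate(predicted: set, reference: set) -> float:
    """F1 = tp / (tp + 0.5 (fp + fn)) over terminal cell-fate types."""
    pred, ref = set(predicted), set(reference)
    if not ref:
        raise DataError("reference terminal set is empty; F1 undefined")
    tp = len(pred & ref)
    fp = len(pred - ref)
    fn = len(ref - pred)
    if tp == 0:
        return 0.0
    return tp / (tp + 0.5 * (fp + fn))


def majority_type_map(
    cluster_labels: np.ndarray, cell_types: np.ndarray
) -> dict[int, str]:
    """Map each cluster to the reference type of the majority of its cells.

    Ties break toward the larger absolute overlap (identical by definition
    within one cluster), then toward the lexicographically smaller type name,
    giving a deterministic assignment.
    """
    cluster_labels = np.asarray(cluster_labels)
    cell_types = np.asarray(cell_types, dtype=object)
    mapping: dict[int, str] = {}
    for c in np.unique(cluster_labels):
        types, counts = np.unique(cell_types[cluster_labels == c], return_counts=True)
        order = sorted(zip(-counts, types))
        mapping[int(c)] = str(order[0][1])
    return mapping


@dataclass
class ScoreReport:
    """All five trajectory metrics plus the composite accuracy."""

    im: float
    ged: int
    ged_max: int
    f1_branch: float
    pearson_time: float
    f1_fate: float | None
    composite: float = field(init=False, default=np.nan)
    included: tuple = field(init=False, default=())

    def __post_init__(self) -> None:
        self.composite, self.included = _composite(self)

    def to_dict(self) -> dict:
        return {
            "im": self.im,
            "ged": self.ged,
            "ged_max": self.ged_max,
            "f1_branch": self.f1_branch,
            "pearson_time": self.pearson_time,
            "f1_fate": self.f1_fate,
            "composite": self.composite,
            "included": list(self.included),
        }


def _composite(report: ScoreReport) -> tuple[float, tuple]:
    include_lineage = report.f1_fate is not None
    parts = {
        "im": 100.0 * (1.0 - report.im),
        "ged": 100.0 * (1.0 - report.ged / max(report.ged_max, 1)),
        "f1_branch": 100.0 * report.f1_branch,
        "pearson_time": 100.0 * max(report.pearson_time, 0.0),
    }
    if include_lineage:
        parts["f1_fate"] = 100.0 * report.f1_fate
    return float(np.mean(list(parts.values()))), tuple(parts)


def composite_score(report: ScoreReport, include_lineage: bool = True) -> float:
    """Arithmetic mean of the percentage-converted metrics (4 or 5 of them)."""
    if include_lineage and report.f1_fate is None:
        raise ParameterError("f1_fate missing but include_lineage requested")
    parts = [
        100.0 * (1.0 - report.im),
        100.0 * (1.0 - report.ged / max(report.ged_max, 1)),
        100.0 * report.f1_branch,
        100.0 * max(report.pearson_time, 0.0),
    ]
    if include_lineage:
        parts.append(100.0 * report.f1_fate)
    return float(np.mean(parts))


def score_trajectory(
    cluster_labels: np.ndarray,
    cluster_edges: list[tuple[int, int]],
    terminal_clusters: list[int],
    t_cells: np.ndarray,
    reference,
    include_lineage: bool = True,
) -> ScoreReport:
    """Score an inferred trajectory against a :class:`ReferenceTrajectory`.

    Clusters are mapped to reference branch types by majority vote; the
    type-level inferred graph is compared with the reference branch-adjacency
    graph (IM, GED, F1-branch); per-cell pseudotime against true time
    (Pearson); predicted terminal branch types against the reference terminal
    branches (F1-fate).
    """
    type_of = majority_type_map(cluster_labels, reference.branch)
    inferred_nodes = sorted(set(type_of.values()))
    inferred_edges = set()
    for u, v in cluster_edges:
        tu, tv = type_of[int(u)], type_of[int(v)]
        if tu != tv:
            inferred_edges.add(frozenset((tu, tv)))
    G_ti = _labeled_graph(inferred_nodes, inferred_edges)
    G_ref = reference.branch_graph()
    for v in G_ref.nodes:
        G_ref.nodes[v]["label"] = v

    im = im_distance(G_ti, G_ref)
    ged = graph_edit_distance(G_ti, G_ref, labeled=True)
    ged_max = (
        G_ti.number_of_nodes() + G_ti.number_of_edges()
        + G_ref.number_of_nodes() + G_ref.number_of_edges()
    )
    f1b = f1_branch(inferred_edges, reference.branch_adjacency())
    rho = temporal_correlation(t_cells, reference.true_time)
    f1f = None
    if include_lineage:
        predicted = {type_of[int(c)] for c in terminal_clusters}
        f1f = f1_fate(predicted, reference.terminal_branches)
    return ScoreReport(im, ged, ged_max, f1b, rho, f1f)
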