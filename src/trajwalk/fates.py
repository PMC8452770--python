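"""Terminal-state detection, lineage likelihoods and single-cell projection.

Terminal cell fates are found by a consensus vote over connectivity
properties of the forward-biased cluster graph; the probability that a
cluster (and, after projection, a cell) belongs to the lineage ending at a
given terminal state is estimated by the visitation frequencies of simulated
lazy-teleporting walks that successfully reach that terminal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .config import WalkConfig
from .errors import DataError, ParameterError
from .graphs import ClusterAssignment, SingleCellKNNGraph
from .walk import DirectedClusterGraph, PseudotimeVector, _simulate_walks


@dataclass
class NodeConnectivity:
    """Per-node out-degree, closeness and betweenness of the forward graph.

    All three are computed on the directed, unweighted (hop-count) view that
    keeps only edge orientations pointing forward in pseudotime.  Closeness
    is ``C(q) = 1 / sum_r l(q, r)`` over the nodes reachable from ``q``
    (0 when none are reachable); betweenness counts, per ordered pair of
    distinct endpoints, the fraction of shortest paths passing through ``q``.
    """

    out_degree: np.ndarray
    closeness: np.ndarray
    betweenness: np.ndarray


def node_connectivity(dg: DirectedClusterGraph | nx.DiGraph) -> NodeConnectivity:
    g = dg.forward_view() if isinstance(dg, DirectedClusterGraph) else dg
    n = g.number_of_nodes()
    if n < 1:
        raise DataError("graph must have at least one node")
    out_degree = np.array([g.out_degree(q) for q in range(n)], dtype=float)
    closeness = np.zeros(n)
    for q in range(n):
        lengths = nx.single_source_shortest_path_length(g, q)
        total = sum(l for node, l in lengths.items() if node != q)
        closeness[q] = 1.0 / total if total > 0 else 0.0
    btw = nx.betweenness_centrality(g, normalized=False)
    betweenness = np.array([btw[q] for q in range(n)])
    return NodeConnectivity(out_degree, closeness, betweenness)


@dataclass
class TerminalStateSet:
    """Detected terminal clusters plus the per-node vote ledger."""

    terminals: list[int]
    ledger: pd.DataFrame


def detect_terminal_states(
    nc: NodeConnectivity,
    t: PseudotimeVector | np.ndarray,
    root: int,
    component_labels: np.ndarray | None = None,
    directions: dict[str, str] | None = None,
    quorum: int = 2,
) -> TerminalStateSet:
    """Consensus vote for terminal states.

    A node is terminal iff (i) its refined pseudotime lies strictly above the
    median of its connected component (the pseudotime gate) and (ii) it wins
    at least ``quorum`` of the three connectivity votes, whose default
    directions are: out-degree at or below the component median, closeness at
    or above, betweenness at or below.  The connectivity comparisons are
    non-strict because on small graphs the leafward extreme (zero out-degree,
    zero betweenness) frequently *is* the median; the pseudotime gate stays
    strict so uniform-time degenerate topologies yield no terminals.  The
    root never qualifies.
    Returns the full vote ledger for auditability; an empty terminal set
    (e.g. a pure cycle with uniform pseudotime) raises a warning.
    """
    tv = t.best() if isinstance(t, PseudotimeVector) else np.asarray(t, dtype=float)
    n = len(tv)
    if not (len(nc.out_degree) == len(nc.closeness) == len(nc.betweenness) == n):
        raise DataError("connectivity metrics and pseudotime cover different node sets")
    comp = np.zeros(n, dtype=int) if component_labels is None else np.asarray(component_labels)
    directions = directions or {"out_degree": "below", "closeness": "above", "betweenness": "below"}

    metric_values = {
        "out_degree": nc.out_degree,
        "closeness": nc.closeness,
        "betweenness": nc.betweenness,
    }
    rows = []
    terminals: list[int] = []
    for c in np.unique(comp):
        members = np.flatnonzero(comp == c)
        timed = members[np.isfinite(tv[members])]
        if len(timed) == 0:
            continue
        t_med = np.median(tv[timed])
        medians = {m: np.median(v[timed]) for m, v in metric_values.items()}
        for q in members:
            gate = bool(np.isfinite(tv[q]) and tv[q] > t_med)
            votes = {}
            for m, v in metric_values.items():
                if directions[m] == "below":
                    votes[m] = bool(v[q] <= medians[m])
                else:
                    votes[m] = bool(v[q] >= medians[m])
            n_votes = sum(votes.values())
            is_terminal = gate and n_votes >= quorum and q != root
            rows.append(
                {
                    "cluster_id": int(q),
                    "component": int(c),
                    "t_refined": float(tv[q]),
                    "pseudotime_gate": gate,
                    "vote_out_degree": votes["out_degree"],
                    "vote_closeness": votes["closeness"],
                    "vote_betweenness": votes["betweenness"],
                    "passed_votes": int(n_votes),
                    "is_terminal": is_terminal,
                }
            )
            if is_terminal:
                terminals.append(int(q))
    ledger = pd.DataFrame(rows).sort_values("cluster_id").reset_index(drop=True)
    if not terminals:
        warnings.warn(
            "no node passed the terminal-state vote (degenerate topology, "
            "e.g. a pure cycle with uniform pseudotime)",
            stacklevel=2,
        )
    return TerminalStateSet(sorted(terminals), ledger)


@dataclass
class LineageMatrix:
    """Visitation-frequency lineage probabilities.

    ``cluster_probs[i, j]`` is the number of visits to cluster ``i`` during
    walks that successfully reached terminal ``j`` divided by the visits to
    ``i`` over all walks of that terminal's simulation batch.
    """

    cluster_probs: np.ndarray  # n_clusters x n_terminals
    terminals: list[int]
    cell_probs: np.ndarray | None = None


def lineage_likelihoods(
    dg: DirectedClusterGraph,
    root: int,
    terminals: TerminalStateSet | list[int],
    cfg: WalkConfig,
) -> LineageMatrix:
    """Monte-Carlo lineage likelihoods toward each terminal state.

    For each terminal ``j``, ``n_mcmc`` lazy-teleporting walks start at the
    root and stop when they reach ``j`` (success) or after ``max_steps``
    (failure).  Repeat visits within one walk all count; a teleport arrival
    counts as a visit.  Terminals never reached get a zero column and a
    warning.
    """
    term = terminals.terminals if isinstance(terminals, TerminalStateSet) else list(terminals)
    n = dg.n_nodes
    probs = np.zeros((n, len(term)))
    for j, target in enumerate(term):
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, j]))
        _, visits, success = _simulate_walks(
            dg, root, cfg, rng, absorb_at=target, count_visits=True
        )
        total = visits.sum(axis=0).astype(float)
        good = visits[success].sum(axis=0).astype(float)
        if not success.any():
            warnings.warn(
                f"terminal {target} unreachable in all {cfg.n_mcmc} walks", stacklevel=2
            )
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            col = np.where(total > 0, good / np.maximum(total, 1e-300), 0.0)
        probs[:, j] = col
    return LineageMatrix(probs, term)


def project_to_cells(
    cluster_values: np.ndarray,
    g: SingleCellKNNGraph,
    a: ClusterAssignment,
    n_smooth: int = 1,
) -> np.ndarray:
    """Project cluster-level values to cells through the single-cell KNN graph.

    Each cell receives the affinity-weighted mean, over its KNN neighbours,
    of the neighbours' cluster values; ``n_smooth`` controls how many
    averaging passes are applied.  Cells with no neighbours keep their own
    cluster's value.  Works for vectors (per-cluster) and matrices
    (clusters x terminals).
    """
    vals = np.asarray(cluster_values, dtype=float)
    squeeze = vals.ndim == 1
    if squeeze:
        vals = vals[:, None]
    if vals.shape[0] != a.n_clusters:
        raise DataError("cluster values must cover all clusters")
    v = vals[a.labels]  # start from each cell's own cluster value
    A = g.adjacency
    rowsum = np.asarray(A.sum(axis=1)).ravel()
    ok = rowsum > 0
    inv = np.zeros_like(rowsum)
    inv[ok] = 1.0 / rowsum[ok]
    T = sp.diags(inv) @ A
    for _ in range(max(0, int(n_smooth))):
        v_next = T @ v
        v_next[~ok] = v[~ok]
        v = v_next
    return v.ravel() if squeeze else v
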