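"""Synthetic single-cell trajectories with known reference topology.

The generator emulates the statistical structure of toy single-cell
benchmarks: cells are placed uniformly along the edges of a small milestone
network (linear, bifurcating, multifurcating, cyclic, connected-hybrid or
disconnected), each feature's mean expression interpolates linearly between
per-milestone archetype levels drawn from a log-normal prior, and counts are
sampled from a negative-binomial (or Gaussian) noise model.  The reference
truth — milestone network, per-cell time, branch labels and terminal fates —
is returned alongside the matrix so every pipeline stage can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .errors import ParameterError
from .graphs import FeatureMatrix

KINDS = ("linear", "bifurcation", "multifurcation", "cyclic", "connected_hybrid", "disconnected")

# milestone networks per topology kind: directed edges; cycles close on their start
_NETWORKS: dict[str, list[tuple[int, int]]] = {
    "linear": [(0, 1), (1, 2), (2, 3), (3, 4)],
    "bifurcation": [(0, 1), (1, 2), (1, 3)],
    # two cascading bifurcations -> four leaves
    "multifurcation": [(0, 1), (1, 2), (1, 3), (2, 4), (2, 5), (3, 6), (3, 7)],
    "cyclic": [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (5, 0)],
    # a cycle with a bifurcating tree hanging off one of its milestones
    "connected_hybrid": [(0, 1), (1, 2), (2, 3), (3, 4), (4, 0), (2, 5), (5, 6), (5, 7)],
    # component A: cycle; component B: bifurcation
    "disconnected": [(0, 1), (1, 2), (2, 3), (3, 0), (4, 5), (5, 6), (5, 7)],
}
_CYCLE_EDGES: dict[str, set[tuple[int, int]]] = {
    "cyclic": {(5, 0)},
    "connected_hybrid": {(4, 0)},
    "disconnected": {(3, 0)},
}


@dataclass
class TopologySpec:
    """What to simulate: topology kind, sizes, noise model and seed."""

    kind: str = "multifurcation"
    n_cells: int = 1000
    n_features: int = 1000
    noise: str = "nb"            # "nb" (negative binomial) or "gaussian"
    dispersion: float = 5.0      # NB size parameter (smaller = noisier)
    sigma: float = 0.3           # Gaussian noise sd (log scale)
    archetype_sd: float = 1.0    # sd of per-milestone log-levels
    marker_frac: float = 0.2     # fraction of features made branch markers
    marker_boost: float = 2.0    # log-level increase along a marker's branch
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ParameterError(f"unknown topology kind {self.kind!r}")
        edges = _NETWORKS[self.kind]
        n_milestones = len({m for e in edges for m in e})
        if self.n_cells < 10 * n_milestones:
            raise ParameterError(
                f"n_cells must be >= 10 * n_milestones ({10 * n_milestones}) for {self.kind}"
            )

    def milestone_network(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_edges_from(_NETWORKS[self.kind])
        return g


@dataclass
class ReferenceTrajectory:
    """Ground truth for scoring: network, times, branches, fates."""

    milestone_network: nx.DiGraph
    true_time: np.ndarray          # per cell, in [0, 1] per component
    branch: np.ndarray             # per cell, edge label "u->v"
    progression: np.ndarray        # per cell, position within its branch
    terminal_milestones: list[int]
    component: np.ndarray          # per cell, component id
    marker_features: dict = field(default_factory=dict)  # feature idx -> branch label

    @property
    def terminal_branches(self) -> set[str]:
        """Branch labels whose edge ends at a terminal milestone."""
        return {
            f"{u}->{v}"
            for u, v in self.milestone_network.edges
            if v in self.terminal_milestones
        }

    def branch_adjacency(self) -> set[frozenset]:
        """Type-level reference edges: branches sharing a milestone."""
        g = self.milestone_network
        out = set()
        for m in g.nodes:
            inc = [f"{u}->{v}" for u, v in g.edges if m in (u, v)]
            for i in range(len(inc)):
                for j in range(i + 1, len(inc)):
                    out.add(frozenset((inc[i], inc[j])))
        return out

    def branch_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(f"{u}->{v}" for u, v in self.milestone_network.edges)
        g.add_edges_from(tuple(e) for e in self.branch_adjacency())
        return g


def _component_roots(g: nx.DiGraph, kind: str) -> dict[int, int]:
    """Pick the time origin of each weakly connected component."""
    roots = {}
    for ci, nodes in enumerate(sorted(nx.weakly_connected_components(g), key=min)):
        sub = g.subgraph(nodes)
        starts = [m for m in sorted(nodes) if sub.in_degree(m) == 0]
        roots[ci] = starts[0] if starts else min(nodes)  # cycles: smallest id
    return roots


def _edge_start_times(g: nx.DiGraph, kind: str) -> tuple[dict, dict, float]:
    """Directed distance from the component root to each edge's start."""
    comp_of = {}
    for ci, nodes in enumerate(sorted(nx.weakly_connected_components(g), key=min)):
        for m in nodes:
            comp_of[m] = ci
    roots = _component_roots(g, kind)
    start_time: dict[tuple[int, int], float] = {}
    max_per_comp: dict[int, float] = {}
    for ci, root in roots.items():
        nodes = [m for m in g.nodes if comp_of[m] == ci]
        sub = g.subgraph(nodes)
        # distance along directed edges; cycle-closing edges extend the path
        dist = {root: 0.0}
        order = list(nx.bfs_tree(sub, root))
        for u in order:
            for v in sub.successors(u):
                cand = dist[u] + 1.0
                if v not in dist or (cand < dist[v] and (u, v) not in _CYCLE_EDGES.get(kind, set())):
                    dist.setdefault(v, cand)
        for u, v in sub.edges:
            start_time[(u, v)] = dist[u]
            max_per_comp[ci] = max(max_per_comp.get(ci, 0.0), dist[u] + 1.0)
    return start_time, comp_of, roots


def write_reference(ref: ReferenceTrajectory, cell_ids, outdir) -> None:
    """Write the milestone edge list (TSV) and the per-cell truth table (CSV)."""
    import pandas as pd
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [{"source": u, "target": v} for u, v in ref.milestone_network.edges]
    ).to_csv(outdir / "milestones.tsv", sep="\t", index=False)
    terminal_branches = ref.terminal_branches
    pd.DataFrame(
        {
            "cell_id": cell_ids,
            "true_time": ref.true_time,
            "branch": ref.branch,
            "progression": ref.progression,
            "component": ref.component,
            "is_terminal_branch": [b in terminal_branches for b in ref.branch],
        }
    ).to_csv(outdir / "truth.csv", index=False, float_format="%.17g")


def read_reference(truth_csv, milestones_tsv) -> tuple[ReferenceTrajectory, np.ndarray]:
    """Rebuild a :class:`ReferenceTrajectory` from its on-disk tables."""
    import pandas as pd

    truth = pd.read_csv(truth_csv)
    edges = pd.read_csv(milestones_tsv, sep="\t")
    g = nx.DiGraph()
    g.add_edges_from(zip(edges["source"].astype(int), edges["target"].astype(int)))
    terminal = [m for m in g.nodes if g.out_degree(m) == 0]
    ref = ReferenceTrajectory(
        g,
        truth["true_time"].to_numpy(float),
        truth["branch"].to_numpy(object),
        truth["progression"].to_numpy(float),
        terminal,
        truth["component"].to_numpy(int),
    )
    return ref, truth["cell_id"].to_numpy(object)


def simulate_trajectory(spec: TopologySpec) -> tuple[FeatureMatrix, ReferenceTrajectory]:
    """Sample a cells x features count matrix along the reference topology.

    Cells are spread uniformly over milestone edges; per-feature means are
    piecewise-linear in the per-milestone archetype log-levels; counts come
    from the configured noise model.  Bit-reproducible for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    g = spec.milestone_network()
    edges = list(g.edges)
    n_edges = len(edges)
    milestones = sorted(g.nodes)
    m_index = {m: i for i, m in enumerate(milestones)}

    start_time, comp_of, _ = _edge_start_times(g, spec.kind)
    comp_max = {}
    for (u, v), st in start_time.items():
        ci = comp_of[u]
        comp_max[ci] = max(comp_max.get(ci, 0.0), st + 1.0)

    # archetype log-levels per milestone; branch markers increase along their edge
    L = rng.normal(0.0, spec.archetype_sd, size=(len(milestones), spec.n_features))
    n_markers = int(spec.marker_frac * spec.n_features)
    marker_edges = rng.integers(0, n_edges, size=n_markers)
    marker_feats = rng.choice(spec.n_features, size=n_markers, replace=False)
    for f, ei in zip(marker_feats, marker_edges):
        u, v = edges[ei]
        L[m_index[v], f] = L[m_index[u], f] + spec.marker_boost

    # place cells uniformly over edges
    edge_of_cell = rng.integers(0, n_edges, size=spec.n_cells)
    s = rng.random(spec.n_cells)
    branch = np.array([f"{edges[e][0]}->{edges[e][1]}" for e in edge_of_cell], dtype=object)
    component = np.array([comp_of[edges[e][0]] for e in edge_of_cell])
    true_time = np.array(
        [
            (start_time[edges[e]] + si) / comp_max[comp_of[edges[e][0]]]
            for e, si in zip(edge_of_cell, s)
        ]
    )

    u_idx = np.array([m_index[edges[e][0]] for e in edge_of_cell])
    v_idx = np.array([m_index[edges[e][1]] for e in edge_of_cell])
    loglevel = (1.0 - s[:, None]) * L[u_idx] + s[:, None] * L[v_idx]
    mu = np.exp(loglevel)
    if spec.noise == "nb":
        theta = spec.dispersion
        p = theta / (theta + mu)
        values = rng.negative_binomial(theta, p).astype(float)
    elif spec.noise == "gaussian":
        values = loglevel + rng.normal(0.0, spec.sigma, size=mu.shape)
    else:
        raise ParameterError(f"unknown noise model {spec.noise!r}")

    terminal = [m for m in milestones if g.out_degree(m) == 0]
    cell_ids = np.array([f"cell_{i}" for i in range(spec.n_cells)], dtype=object)
    feat_ids = np.array([f"gene_{j}" for j in range(spec.n_features)], dtype=object)
    X = FeatureMatrix(values, cell_ids, feat_ids)
    markers = {
        int(f): f"{edges[ei][0]}->{edges[ei][1]}"
        for f, ei in zip(marker_feats, marker_edges)
    }
    ref = ReferenceTrajectory(g, true_time, branch, s, terminal, component, markers)
    return X, ref
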