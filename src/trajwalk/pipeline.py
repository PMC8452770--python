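"""End-to-end trajectory inference: matrix in, trajectory tables out.

Stages: optional log1p + PCA, exact KNN graph, clustering, cluster graph,
per-component root resolution, closed-form hitting-time pseudotime, logistic
forward bias, MCMC refinement, terminal-state vote, lineage likelihoods,
single-cell projection and feature trends.  Every stochastic stage derives
its randomness from the single configured seed, so identical configurations
produce byte-identical outputs.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from . import io as tio
from .config import PipelineConfig, WalkConfig
from .errors import ParameterError
from .fates import (
    LineageMatrix,
    TerminalStateSet,
    detect_terminal_states,
    lineage_likelihoods,
    node_connectivity,
    project_to_cells,
)
from .graphs import (
    ClusterAssignment,
    ClusterGraph,
    FeatureMatrix,
    RootSpec,
    SingleCellKNNGraph,
    build_cluster_graph,
    build_knn_graph,
    cluster_cells,
    select_root,
)
from .trends import TrendCurve, impute_features, lineage_trend
from .walk import (
    DirectedClusterGraph,
    PseudotimeVector,
    forward_bias_edges,
    mcmc_refine_pseudotime,
    spectral_cache,
    closed_form_hitting_times,
)

log = logging.getLogger("trajwalk")


@dataclass
class TrajectoryResult:
    """Everything the pipeline computed, cluster- and cell-level."""

    X: FeatureMatrix
    knn: SingleCellKNNGraph
    assignment: ClusterAssignment
    cluster_graph: ClusterGraph
    roots: dict[int, int]                  # component -> root cluster
    pseudotime: PseudotimeVector           # cluster level
    directed_graph: DirectedClusterGraph
    terminals: TerminalStateSet
    lineages: LineageMatrix
    t_cells: np.ndarray                    # refined pseudotime per cell
    component_of_cluster: np.ndarray
    trends: list[TrendCurve] = field(default_factory=list)

    def pseudotime_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cluster_id": np.arange(self.cluster_graph.n_nodes),
                "component": self.component_of_cluster,
                "t_closed": self.pseudotime.t_closed,
                "t_refined": self.pseudotime.t_refined,
            }
        )


def _other_component_root(
    cg: ClusterGraph, nodes: np.ndarray, a: ClusterAssignment,
    annotations: np.ndarray | None,
) -> int:
    """Root for a component that does not contain the user's root.

    With annotations: the component's cluster richest in the globally
    earliest label is not identifiable without extra input, so the fallback
    is structural — the node with maximal eccentricity in the component
    (ties to the lowest id), i.e. a peripheral state.
    """
    sub = cg.subgraph(nodes).to_networkx()
    if sub.number_of_nodes() == 1:
        return int(nodes[0])
    ecc = {}
    import networkx as nx

    for local, node in enumerate(nodes):
        lengths = nx.single_source_shortest_path_length(sub, local)
        ecc[local] = max(lengths.values())
    best = max(sorted(ecc), key=lambda k: ecc[k])
    return int(nodes[best])


def infer_trajectory(
    X: FeatureMatrix,
    cfg: PipelineConfig,
    annotations: np.ndarray | None = None,
) -> TrajectoryResult:
    """Run the full inference on an already-loaded feature matrix."""
    t0 = time.perf_counter()
    wcfg = cfg.walk_config()

    V = X.dense()
    if cfg.log1p:
        V = np.log1p(V)
    if cfg.n_pcs and 0 < cfg.n_pcs < min(V.shape):
        V = PCA(n_components=cfg.n_pcs, svd_solver="full").fit_transform(
            V - V.mean(axis=0)
        )
    Xred = FeatureMatrix.from_array(V, X.cell_ids, [f"PC{i+1}" for i in range(V.shape[1])])
    log.info("preprocess: %d cells x %d dims", Xred.n_cells, Xred.n_features)

    knn = build_knn_graph(Xred, K=cfg.knn, metric=cfg.metric)
    assignment = cluster_cells(
        g=knn, X=Xred, method=cfg.clustering,
        resolution=cfg.resolution, k=cfg.kmeans_k, seed=cfg.seed,
    )
    cg = build_cluster_graph(knn, assignment)
    n_comp, comp = cg.components()
    log.info("cluster graph: %d nodes, %d components", cg.n_nodes, n_comp)

    root_spec = RootSpec(cfg.root_mode, cfg.root_value)
    main_root = select_root(cg, assignment, root_spec, annotations)

    t_closed = np.full(cg.n_nodes, np.nan)
    t_refined = np.full(cg.n_nodes, np.nan)
    mult = np.full((cg.n_nodes, cg.n_nodes), 0.5)
    np.fill_diagonal(mult, 0.0)
    roots: dict[int, int] = {}
    for ci in range(n_comp):
        nodes = np.flatnonzero(comp == ci)
        if comp[main_root] == ci:
            root = main_root
        else:
            root = _other_component_root(cg, nodes, assignment, annotations)
            log.info("component %d lacks the user root; using cluster %d", ci, root)
        roots[ci] = root
        sub = cg.subgraph(nodes)
        local_root = int(np.flatnonzero(nodes == root)[0])
        if len(nodes) == 1:
            t_closed[nodes] = 0.0
            t_refined[nodes] = 0.0
            continue
        cache = spectral_cache(sub, wcfg, component_of=local_root)
        tc = closed_form_hitting_times(cache, sub, local_root, scale="steps")
        sub_dg = forward_bias_edges(sub, tc, wcfg, time_scale=cfg.time_scale)
        tr = mcmc_refine_pseudotime(sub_dg, local_root, wcfg)
        t_closed[nodes] = tc
        t_refined[nodes] = tr
        mult[np.ix_(nodes, nodes)] = sub_dg.multipliers
    pseudotime = PseudotimeVector(t_closed, t_refined, main_root)
    dg = DirectedClusterGraph(cg.W.copy(), mult, t_refined)

    nc = node_connectivity(dg)
    terminals = detect_terminal_states(nc, pseudotime, main_root, component_labels=comp)
    # lineages per component, from that component's root
    probs = np.zeros((cg.n_nodes, len(terminals.terminals)))
    for ci in range(n_comp):
        nodes = np.flatnonzero(comp == ci)
        terms_here = [t for t in terminals.terminals if comp[t] == ci]
        if not terms_here:
            continue
        sub = cg.subgraph(nodes)
        local = {g: i for i, g in enumerate(nodes)}
        sub_dg = DirectedClusterGraph(
            sub.W, mult[np.ix_(nodes, nodes)], t_refined[nodes]
        )
        lm = lineage_likelihoods(
            sub_dg, local[roots[ci]], [local[t] for t in terms_here], wcfg
        )
        for j_local, t_global in enumerate(terms_here):
            j = terminals.terminals.index(t_global)
            probs[nodes, j] = lm.cluster_probs[:, j_local]
    cell_probs = (
        project_to_cells(probs, knn, assignment, n_smooth=cfg.n_smooth)
        if probs.size
        else np.zeros((X.n_cells, 0))
    )
    lineages = LineageMatrix(probs, terminals.terminals, cell_probs)

    t_cells = project_to_cells(
        np.nan_to_num(t_refined, nan=float(np.nanmax(t_refined))),
        knn, assignment, n_smooth=cfg.n_smooth,
    )

    trends: list[TrendCurve] = []
    feat_names = cfg.trend_features
    if feat_names:
        imputed = impute_features(X, knn, cfg.t_steps)
        name_to_col = {str(f): j for j, f in enumerate(X.feature_ids)}
        for name in feat_names:
            if name not in name_to_col:
                raise ParameterError(f"unknown trend feature {name!r}")
            col = imputed.dense()[:, name_to_col[name]]
            for j, term in enumerate(terminals.terminals):
                w = cell_probs[:, j]
                if not np.any(w > 0):
                    continue
                trends.append(
                    lineage_trend(col, t_cells, w, lineage=f"{name}_to_{term}")
                )

    log.info("inference finished in %.1fs", time.perf_counter() - t0)
    return TrajectoryResult(
        X, knn, assignment, cg, roots, pseudotime, dg, terminals, lineages,
        t_cells, comp, trends,
    )


def run_pipeline(cfg: PipelineConfig) -> TrajectoryResult:
    """Load the input, infer the trajectory and write the result bundle."""
    X = tio.read_matrix(cfg.input_path, cfg.input_format)
    annotations = None
    if cfg.annotations_path:
        ann = pd.read_csv(cfg.annotations_path)
        annotations = ann.iloc[:, -1].to_numpy(object)
    result = infer_trajectory(X, cfg, annotations)

    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tio.write_cluster_assignment(result.assignment, X.cell_ids, outdir / "clusters.csv")
    tio.write_cluster_graph(result.cluster_graph, outdir / "cluster_graph.tsv")
    tio.write_directed_graph(result.directed_graph, outdir / "directed_graph.tsv")
    tio.write_pseudotime(result.pseudotime_frame(), outdir / "pseudotime.csv")
    pd.DataFrame(
        {"cell_id": X.cell_ids, "t_refined": result.t_cells}
    ).to_csv(outdir / "pseudotime_cells.csv", index=False, float_format="%.17g")
    result.terminals.ledger.to_csv(outdir / "terminal_states.csv", index=False)
    term_cols = [f"terminal_{t}" for t in result.lineages.terminals]
    pd.DataFrame(
        result.lineages.cluster_probs,
        index=pd.Index(range(result.cluster_graph.n_nodes), name="cluster_id"),
        columns=term_cols,
    ).to_csv(outdir / "lineage_clusters.csv", float_format="%.17g")
    pd.DataFrame(
        result.lineages.cell_probs, index=pd.Index(X.cell_ids, name="cell_id"),
        columns=term_cols,
    ).to_csv(outdir / "lineage_cells.csv", float_format="%.17g")
    for curve in result.trends:
        pd.DataFrame({"grid_t": curve.grid, "fitted_value": curve.fitted}).to_csv(
            outdir / f"trend_{curve.lineage}.csv", index=False, float_format="%.17g"
        )
    tio.write_manifest(
        outdir / "manifest.json",
        cfg.to_dict(),
        extra={
            "n_clusters": int(result.assignment.n_clusters),
            "terminals": [int(t) for t in result.terminals.terminals],
            "roots": {str(k): int(v) for k, v in result.roots.items()},
        },
    )
    return result
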