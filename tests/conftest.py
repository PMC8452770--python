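"""Shared fixtures: small deterministic graphs and simulated datasets.

Heavy end-to-end runs (1000-cell simulations plus full inference) are
session-scoped so they are computed once and shared across tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import trajwalk as tw


def random_connected_graph(n: int, rng: np.random.Generator) -> tw.ClusterGraph:
    """Random connected weighted graph for oracle sweeps."""
    while True:
        W = np.triu((rng.random((n, n)) < 0.6) * (0.2 + rng.random((n, n))), 1)
        W = W + W.T
        A = (W > 0) + np.eye(n, dtype=bool)
        if (np.linalg.matrix_power(A, n) > 0).all():
            return tw.ClusterGraph(W)


def hitting_time_oracle(cg: tw.ClusterGraph, cfg: tw.WalkConfig, root: int) -> np.ndarray:
    """Dense first-hitting linear system (I - Q) h = 1 on the Z' chain."""
    ops = tw.transition_operators(cg, cfg)
    n = cg.n_nodes
    out = np.zeros(n)
    for r in range(n):
        if r == root:
            continue
        idx = [i for i in range(n) if i != r]
        Q = ops.Zprime[np.ix_(idx, idx)]
        h = np.linalg.solve(np.eye(n - 1) - Q, np.ones(n - 1))
        out[r] = h[idx.index(root)]
    return out


@pytest.fixture(scope="session")
def two_blobs():
    """Two tight Gaussian blobs 10 units apart: unambiguous two-cluster data."""
    rng = np.random.default_rng(0)
    V = np.vstack([rng.normal(0.0, 0.1, (50, 3)), rng.normal(10.0, 0.1, (50, 3))])
    truth = np.repeat([0, 1], 50)
    return tw.FeatureMatrix.from_array(V), truth


@pytest.fixture(scope="session")
def multifurc_data():
    spec = tw.TopologySpec(kind="multifurcation", seed=1)
    return tw.simulate_trajectory(spec)


@pytest.fixture(scope="session")
def multifurc_result(multifurc_data):
    X, ref = multifurc_data
    cfg = tw.PipelineConfig(
        root_mode="cell_index", root_value=int(np.argmin(ref.true_time)), seed=42
    )
    return tw.infer_trajectory(X, cfg)


@pytest.fixture(scope="session")
def linear_data():
    spec = tw.TopologySpec(kind="linear", seed=4)
    return tw.simulate_trajectory(spec)


@pytest.fixture(scope="session")
def linear_result(linear_data):
    X, ref = linear_data
    cfg = tw.PipelineConfig(
        root_mode="cell_index", root_value=int(np.argmin(ref.true_time)), seed=42
    )
    return tw.infer_trajectory(X, cfg)


@pytest.fixture(scope="session")
def cyclic_data():
    spec = tw.TopologySpec(kind="cyclic", seed=2)
    return tw.simulate_trajectory(spec)


@pytest.fixture(scope="session")
def disconnected_data():
    spec = tw.TopologySpec(kind="disconnected", seed=3)
    return tw.simulate_trajectory(spec)


@pytest.fixture
def small_matrix():
    rng = np.random.default_rng(5)
    return tw.FeatureMatrix.from_array(rng.poisson(3.0, size=(12, 6)).astype(float))
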