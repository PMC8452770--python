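"""Random-walk operators, closed-form hitting times and MCMC refinement."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import trajwalk as tw
from trajwalk.errors import DegenerateParameterError
from trajwalk.walk import DirectedClusterGraph

from conftest import hitting_time_oracle, random_connected_graph


def two_node_graph():
    return tw.ClusterGraph(np.array([[0.0, 1.0], [1.0, 0.0]]))


class TestTransitionOperators:
    def test_two_node_swap(self):
        ops = tw.transition_operators(two_node_graph(), tw.WalkConfig())
        assert np.allclose(ops.P, [[0, 1], [1, 0]])

    def test_no_laziness_no_teleport_collapses_to_p(self):
        cfg = tw.WalkConfig(x=1.0, alpha=1.0)
        ops = tw.transition_operators(two_node_graph(), cfg)
        assert np.allclose(ops.Zprime, ops.P)

    def test_triangle_lazy_diagonal(self):
        W = np.ones((3, 3)) - np.eye(3)
        ops = tw.transition_operators(tw.ClusterGraph(W), tw.WalkConfig(x=0.5, alpha=1.0))
        assert np.allclose(np.diag(ops.Z), 0.5)
        assert np.allclose(ops.Z[0, 1:], 0.25)
        assert np.allclose(ops.Z.sum(axis=1), 1.0)

    @settings(deadline=None, max_examples=15)
    @given(st.integers(0, 10_000))
    def test_rows_stochastic_and_nonnegative(self, seed):
        rng = np.random.default_rng(seed)
        cg = random_connected_graph(int(rng.integers(2, 8)), rng)
        ops = tw.transition_operators(cg, tw.WalkConfig(x=0.8, alpha=0.9))
        for M in (ops.P, ops.Z, ops.Zprime):
            assert np.allclose(M.sum(axis=1), 1.0, atol=1e-12)
            assert M.min() >= 0


class TestSpectralCache:
    def test_beta_formula(self):
        cg = two_node_graph()
        assert tw.spectral_cache(cg, tw.WalkConfig(alpha=1e-12)).beta == pytest.approx(1.0)
        assert tw.spectral_cache(cg, tw.WalkConfig(alpha=0.5)).beta == pytest.approx(2 * 0.5 / 1.5)

    def test_alpha_one_is_degenerate(self):
        with pytest.raises(DegenerateParameterError):
            tw.spectral_cache(two_node_graph(), tw.WalkConfig(alpha=1.0))

    def test_two_node_analytic_eigenpairs(self):
        cfg = tw.WalkConfig(x=0.9, alpha=0.9)
        cache = tw.spectral_cache(two_node_graph(), cfg)
        assert np.allclose(np.sort(cache.eta), [0.0, 2.0])
        beta = cache.beta
        v1 = np.array([1.0, 1.0]) / np.sqrt(2)   # eta = 0
        v2 = np.array([1.0, -1.0]) / np.sqrt(2)  # eta = 2
        R_hand = np.outer(v1, v1) / beta + np.outer(v2, v2) / (beta + 4 * cfg.x * (1 - beta))
        assert np.allclose(cache.R, R_hand, atol=1e-12)


class TestClosedFormHittingTimes:
    def test_root_time_is_zero(self):
        rng = np.random.default_rng(0)
        cg = random_connected_graph(6, rng)
        cfg = tw.WalkConfig()
        t = tw.closed_form_hitting_times(tw.spectral_cache(cg, cfg), cg, root=2)
        assert t[2] == 0.0

    def test_two_node_matches_linear_system(self):
        cfg = tw.WalkConfig(x=0.9, alpha=0.95)
        cg = two_node_graph()
        t = tw.closed_form_hitting_times(tw.spectral_cache(cg, cfg), cg, root=0)
        oracle = hitting_time_oracle(cg, cfg, root=0)
        assert t[1] == pytest.approx(oracle[1], rel=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_oracle_sweep_small_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 11))
        cg = random_connected_graph(n, rng)
        cfg = tw.WalkConfig(x=0.95, alpha=0.99)
        t = tw.closed_form_hitting_times(tw.spectral_cache(cg, cfg), cg, root=0)
        oracle = hitting_time_oracle(cg, cfg, root=0)
        rel = np.abs(t[1:] - oracle[1:]) / oracle[1:]
        assert rel.max() < 1e-8

    def test_near_classical_limit_on_path(self):
        # alpha, x -> 1: expected hitting time from the end of an unweighted
        # path to node k approaches the classical k^2 law
        n = 5
        W = np.zeros((n, n))
        for i in range(n - 1):
            W[i, i + 1] = W[i + 1, i] = 1.0
        cg = tw.ClusterGraph(W)
        cfg = tw.WalkConfig(x=1.0, alpha=1 - 1e-9)
        t = tw.closed_form_hitting_times(tw.spectral_cache(cg, cfg), cg, root=0)
        classical = np.array([float(k * k) for k in range(n)])
        assert np.allclose(t[1:], classical[1:], rtol=1e-3)


class TestForwardBias:
    def test_equal_times_give_half(self):
        cg = two_node_graph()
        dg = tw.forward_bias_edges(cg, np.array([1.0, 1.0]), tw.WalkConfig())
        assert dg.multipliers[0, 1] == pytest.approx(0.5)
        assert dg.multipliers[1, 0] == pytest.approx(0.5)

    def test_log3_gap_gives_three_quarters(self):
        cg = two_node_graph()
        dg = tw.forward_bias_edges(cg, np.array([0.0, np.log(3)]), tw.WalkConfig(b=1.0))
        assert dg.multipliers[0, 1] == pytest.approx(0.75)
        assert dg.multipliers[1, 0] == pytest.approx(0.25)

    def test_monotone_path_forward_exceeds_reverse(self):
        n = 6
        W = np.zeros((n, n))
        for i in range(n - 1):
            W[i, i + 1] = W[i + 1, i] = 1.0
        dg = tw.forward_bias_edges(tw.ClusterGraph(W), np.arange(n, dtype=float), tw.WalkConfig())
        for i in range(n - 1):
            assert dg.W_directed[i, i + 1] > dg.W_directed[i + 1, i]

    @settings(deadline=None, max_examples=15)
    @given(st.integers(0, 10_000))
    def test_orientation_multipliers_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        cg = random_connected_graph(int(rng.integers(2, 8)), rng)
        t = rng.random(cg.n_nodes) * 10
        dg = tw.forward_bias_edges(cg, t, tw.WalkConfig(b=1.0))
        mask = cg.W > 0
        assert np.allclose((dg.multipliers + dg.multipliers.T)[mask], 1.0)


class TestMcmcRefine:
    def _chain(self):
        # hard-directed chain root -> A -> B
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 1.0
        W[1, 2] = W[2, 1] = 1.0
        M = np.zeros((3, 3))
        M[0, 1] = M[1, 2] = 1.0
        return DirectedClusterGraph(W, M, np.array([0.0, 1.0, 2.0]))

    def test_deterministic_chain_steps(self):
        cfg = tw.WalkConfig(x=1.0, alpha=1.0, n_mcmc=50, max_steps=10, seed=0)
        t = tw.mcmc_refine_pseudotime(self._chain(), 0, cfg)
        assert t[0] == 0.0
        assert t[1] == pytest.approx(1.0)
        assert t[2] == pytest.approx(2.0)

    def test_root_always_zero(self):
        rng = np.random.default_rng(1)
        cg = random_connected_graph(6, rng)
        cfg = tw.WalkConfig(n_mcmc=200, seed=3)
        pt, _ = tw.compute_pseudotime(cg, 2, cfg)
        assert pt.t_refined[2] == 0.0

    def test_binary_tree_depth_ordering(self):
        # balanced binary tree of depth 2, forward-directed
        W = np.zeros((7, 7))
        edges = [(0, 1), (0, 2), (1, 3), (1, 4), (2, 5), (2, 6)]
        for i, j in edges:
            W[i, j] = W[j, i] = 1.0
        M = np.zeros((7, 7))
        for i, j in edges:
            M[i, j] = 1.0
        dg = DirectedClusterGraph(W, M, np.array([0.0, 1, 1, 2, 2, 2, 2]))
        cfg = tw.WalkConfig(x=1.0, alpha=1.0, n_mcmc=10_000, max_steps=30, seed=9)
        t = tw.mcmc_refine_pseudotime(dg, 0, cfg)
        assert t[0] < min(t[1], t[2])
        assert max(t[1], t[2]) < min(t[3:])
        assert min(t[3:]) >= 2.0  # a depth-2 node cannot be hit before step 2

    def test_reproducible_under_fixed_seed(self):
        rng = np.random.default_rng(2)
        cg = random_connected_graph(7, rng)
        cfg = tw.WalkConfig(n_mcmc=300, seed=5)
        pt1, _ = tw.compute_pseudotime(cg, 0, cfg)
        pt2, _ = tw.compute_pseudotime(cg, 0, cfg)
        assert np.array_equal(pt1.t_refined, pt2.t_refined)
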