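"""KNN graph, clustering, cluster-graph aggregation and root selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import adjusted_rand_score

import trajwalk as tw
from trajwalk.errors import DataError, LookupFailure, ParameterError


class TestBuildKnnGraph:
    def test_collinear_nearest_neighbors(self):
        X = tw.FeatureMatrix.from_array(np.array([[0.0], [1.0], [10.0]]))
        g = tw.build_knn_graph(X, K=1)
        assert g.neighbor_indices[1, 0] == 0
        assert g.neighbor_indices[2, 0] == 1

    def test_adjacency_symmetric(self, two_blobs):
        X, _ = two_blobs
        g = tw.build_knn_graph(X, K=7)
        assert (abs(g.adjacency - g.adjacency.T)).nnz == 0

    def test_separated_blobs_have_no_cross_edges(self, two_blobs):
        X, truth = two_blobs
        g = tw.build_knn_graph(X, K=5)
        # brute-force: every neighbour must lie in the same blob
        A = g.adjacency.tocoo()
        assert np.all(truth[A.row] == truth[A.col])

    @pytest.mark.parametrize("K", [0, -1, 100])
    def test_invalid_k_rejected(self, K):
        X = tw.FeatureMatrix.from_array(np.random.default_rng(0).random((10, 2)))
        with pytest.raises(ParameterError):
            tw.build_knn_graph(X, K=K)

    def test_nonfinite_input_rejected(self):
        V = np.ones((5, 2))
        V[0, 0] = np.nan
        with pytest.raises(DataError):
            tw.FeatureMatrix.from_array(V)

    @settings(deadline=None, max_examples=20)
    @given(st.integers(0, 10_000))
    def test_symmetrization_property(self, seed):
        rng = np.random.default_rng(seed)
        X = tw.FeatureMatrix.from_array(rng.random((15, 3)))
        g = tw.build_knn_graph(X, K=4)
        diff = g.adjacency - g.adjacency.T
        assert abs(diff).max() < 1e-15
        assert g.adjacency.diagonal().sum() == 0.0


class TestClusterCells:
    def test_kmeans_exact_separation(self):
        X = tw.FeatureMatrix.from_array(np.array([[0.0], [0.0], [10.0], [10.0]]))
        a = tw.cluster_cells(X=X, method="kmeans", k=2, seed=0)
        assert a.n_clusters == 2
        assert a.labels[0] == a.labels[1]
        assert a.labels[2] == a.labels[3]
        assert a.labels[0] != a.labels[2]

    def test_community_detection_respects_components(self, two_blobs):
        X, truth = two_blobs
        g = tw.build_knn_graph(X, K=5)
        a = tw.cluster_cells(g=g, method="community_detection", seed=0)
        # no cluster spans the two disconnected blobs
        for c in range(a.n_clusters):
            assert len(np.unique(truth[a.labels == c])) == 1

    def test_two_blob_assignment_matches_generator(self, two_blobs):
        X, truth = two_blobs
        a = tw.cluster_cells(X=X, method="kmeans", k=2, seed=0)
        assert adjusted_rand_score(truth, a.labels) == 1.0

    def test_permutation_equivariance(self, two_blobs):
        X, _ = two_blobs
        rng = np.random.default_rng(3)
        perm = rng.permutation(X.n_cells)
        a1 = tw.cluster_cells(X=X, method="kmeans", k=2, seed=0)
        Xp = tw.FeatureMatrix.from_array(X.dense()[perm])
        a2 = tw.cluster_cells(X=Xp, method="kmeans", k=2, seed=0)
        assert adjusted_rand_score(a1.labels[perm], a2.labels) == 1.0

    def test_deterministic_given_seed(self, two_blobs):
        X, _ = two_blobs
        g = tw.build_knn_graph(X, K=5)
        a1 = tw.cluster_cells(g=g, method="community_detection", seed=11)
        a2 = tw.cluster_cells(g=g, method="community_detection", seed=11)
        assert np.array_equal(a1.labels, a2.labels)


class TestBuildClusterGraph:
    def test_single_cluster_gives_one_node_no_edges(self, two_blobs):
        X, _ = two_blobs
        g = tw.build_knn_graph(X, K=5)
        a = tw.ClusterAssignment(np.zeros(X.n_cells, dtype=int))
        cg = tw.build_cluster_graph(g, a)
        assert cg.n_nodes == 1
        assert cg.edges() == []

    def test_sum_aggregation_arithmetic(self):
        # 2 clusters joined by exactly 3 unit-weight single-cell edges
        import scipy.sparse as sp

        n = 6
        rows = [0, 1, 2]
        cols = [3, 4, 5]
        A = sp.csr_matrix((np.ones(3), (rows, cols)), shape=(n, n))
        A = A + A.T
        g = tw.SingleCellKNNGraph(
            neighbor_indices=np.zeros((n, 1), int),
            neighbor_weights=np.ones((n, 1)),
            adjacency=A.tocsr(),
            K=1,
            metric="euclidean",
        )
        a = tw.ClusterAssignment(np.array([0, 0, 0, 1, 1, 1]))
        cg = tw.build_cluster_graph(g, a, aggregation="sum")
        assert cg.W[0, 1] == pytest.approx(3.0)

    def test_two_blob_cluster_graph_two_components(self, two_blobs):
        X, truth = two_blobs
        g = tw.build_knn_graph(X, K=5)
        a = tw.ClusterAssignment(truth.astype(int))
        cg = tw.build_cluster_graph(g, a)
        assert cg.n_nodes == 2
        assert cg.components()[0] == 2
        assert cg.W[0, 1] == 0.0

    def test_weight_conservation(self, two_blobs):
        X, _ = two_blobs
        g = tw.build_knn_graph(X, K=5)
        a = tw.cluster_cells(g=g, method="community_detection", seed=0)
        cg = tw.build_cluster_graph(g, a)
        # sum of cluster edges == sum of inter-cluster single-cell weights
        A = g.adjacency.tocoo()
        inter = 0.5 * sum(
            w for i, j, w in zip(A.row, A.col, A.data) if a.labels[i] != a.labels[j]
        )
        total = sum(w for _, _, w in cg.edges())
        assert total == pytest.approx(inter, rel=1e-10)

    def test_components_map_to_components(self, two_blobs):
        X, _ = two_blobs
        g = tw.build_knn_graph(X, K=5)
        a = tw.cluster_cells(g=g, method="community_detection", seed=0)
        cg = tw.build_cluster_graph(g, a)
        assert cg.components()[0] == g.components()[0]


class TestSelectRoot:
    def _toy(self):
        # clusters 0..4 on a path-ish graph; 2 cells per cluster
        W = np.zeros((5, 5))
        for i, j in [(0, 1), (0, 2), (1, 2), (2, 3), (3, 4)]:
            W[i, j] = W[j, i] = 1.0
        cg = tw.ClusterGraph(W)
        a = tw.ClusterAssignment(np.repeat(np.arange(5), 2))
        return cg, a

    def test_cell_index_lookup(self):
        cg, a = self._toy()
        assert tw.select_root(cg, a, tw.RootSpec("cell_index", 7)) == 3

    def test_group_label_unique_majority(self):
        cg, a = self._toy()
        ann = np.array(["x"] * 10, dtype=object)
        ann[6] = ann[7] = "HSC"  # cluster 3 is 100% ... 2 of 2 cells
        assert tw.select_root(cg, a, tw.RootSpec("group_label", "HSC"), ann) == 3

    def test_tie_break_prefers_high_degree_low_betweenness(self):
        cg, a = self._toy()
        # clusters 0 (degree 2) and 4 (degree 1) tie at 50% HSC
        ann = np.array(["x"] * 10, dtype=object)
        ann[0] = "HSC"  # cluster 0: 1 of 2
        ann[8] = "HSC"  # cluster 4: 1 of 2
        assert tw.select_root(cg, a, tw.RootSpec("group_label", "HSC"), ann) == 0

    def test_missing_label_raises(self):
        cg, a = self._toy()
        ann = np.array(["x"] * 10, dtype=object)
        with pytest.raises(LookupFailure):
            tw.select_root(cg, a, tw.RootSpec("group_label", "absent"), ann)
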