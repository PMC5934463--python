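"""Thresholded functional networks and graph measures."""

import numpy as np
import pytest

import vforg as v
from _oracles import naive_weighted_clustering
from conftest import random_correlation_matrix


def net_from_offdiag(values, theta):
    """3x3 correlation matrix with given off-diagonals, thresholded."""
    a, b, c = values
    R = np.array([[1.0, a, b], [a, 1.0, c], [b, c, 1.0]])
    return v.threshold_network(R, theta)


def triangle(w=1.0):
    R = np.full((3, 3), w)
    np.fill_diagonal(R, 1.0)
    return v.threshold_network(R, 0.0)


class TestThresholding:
    def test_absolute_value_rule(self):
        net = net_from_offdiag([0.8, -0.75, 0.3], theta=0.7)
        assert net.n_edges == 2
        weights = sorted(w for _, _, w in net.edge_list())
        assert weights == pytest.approx([0.75, 0.8])

    def test_theta_zero_gives_complete_graph(self):
        rng = np.random.default_rng(0)
        net = v.threshold_network(random_correlation_matrix(rng, 6), 0.0)
        assert net.n_edges == 6 * 5 // 2
        assert not net.A.diagonal().any()

    def test_theta_one_without_perfect_correlations_gives_empty_graph(self):
        net = net_from_offdiag([0.9, -0.99, 0.5], theta=1.0)
        assert net.n_edges == 0

    def test_rejects_theta_outside_unit_interval(self):
        with pytest.raises(v.ParameterError):
            net_from_offdiag([0.5, 0.5, 0.5], theta=1.5)


class TestDensityAndStrength:
    def test_density_triangle_path_empty(self):
        assert v.connection_density(triangle()) == 1.0
        path = net_from_offdiag([0.9, 0.0, 0.9], theta=0.5)  # edges 0-1, 1-2
        assert v.connection_density(path) == pytest.approx(2 / 3)
        assert v.connection_density(net_from_offdiag([0, 0, 0], 0.5)) == 0.0

    def test_density_rejects_single_node(self):
        net = v.FunctionalNetwork(A=np.zeros((1, 1)), W=np.zeros((1, 1)), threshold=0.5)
        with pytest.raises(v.ParameterError):
            v.connection_density(net)

    def test_strength_uniform_triangle(self):
        np.testing.assert_allclose(v.node_strength(triangle(0.5)), [1.0, 1.0, 1.0])

    def test_strength_star(self):
        R = np.eye(4)
        R[0, 1:] = R[1:, 0] = 0.2
        S = v.node_strength(v.threshold_network(R, 0.1))
        np.testing.assert_allclose(S, [0.6, 0.2, 0.2, 0.2])

    def test_strength_empty_graph_is_zero(self):
        assert not v.node_strength(net_from_offdiag([0, 0, 0], 0.5)).any()


class TestClusteringCoefficient:
    def test_binary_complete_triangle(self):
        C_local, C = v.clustering_coefficients(triangle(1.0))
        np.testing.assert_allclose(C_local, 1.0)
        assert C == 1.0

    def test_path_has_no_triangles(self):
        _, C = v.clustering_coefficients(net_from_offdiag([0.9, 0.0, 0.9], 0.5))
        assert C == 0.0

    def test_weighted_triangle_hand_value(self):
        # weights 0.9/0.6/0.3 -> normalized 1, 2/3, 1/3; each node holds one
        # triangle of intensity (1 * 2/3 * 1/3)^(1/3)
        net = net_from_offdiag([0.9, 0.6, 0.3], theta=0.1)
        C_local, C = v.clustering_coefficients(net)
        expected = (1.0 * (2 / 3) * (1 / 3)) ** (1 / 3)
        np.testing.assert_allclose(C_local, expected, atol=1e-12)
        assert C == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_triple_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        net = v.threshold_network(random_correlation_matrix(rng, n), 0.4)
        C_local, _ = v.clustering_coefficients(net)
        np.testing.assert_allclose(
            C_local, naive_weighted_clustering(net.A, net.W), atol=1e-12
        )

    @pytest.mark.parametrize("seed", range(4))
    def test_binary_weights_reduce_to_unweighted_coefficient(self, seed):
        nx = pytest.importorskip("networkx")
        rng = np.random.default_rng(50 + seed)
        A = rng.random((8, 8)) < 0.4
        A = np.triu(A, 1)
        A = A | A.T
        net = v.FunctionalNetwork(A=A, W=A.astype(float), threshold=0.5)
        C_local, _ = v.clustering_coefficients(net)
        G = nx.from_numpy_array(A.astype(int))
        expected = np.array([nx.clustering(G, i) for i in range(8)])
        np.testing.assert_allclose(C_local, expected, atol=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_networkx_weighted_clustering(self, seed):
        nx = pytest.importorskip("networkx")
        rng = np.random.default_rng(80 + seed)
        net = v.threshold_network(random_correlation_matrix(rng, 9), 0.3)
        C_local, _ = v.clustering_coefficients(net)
        G = nx.from_numpy_array(net.W)
        expected = np.array([nx.clustering(G, i, weight="weight") for i in range(9)])
        np.testing.assert_allclose(C_local, expected, atol=1e-12)

    def test_empty_network_has_zero_average(self):
        _, C = v.clustering_coefficients(net_from_offdiag([0, 0, 0], 0.5))
        assert C == 0.0


class TestThresholdSweep:
    def test_density_auc_saturated_matrix(self):
        R = np.ones((4, 4))
        assert v.auc_over_thresholds(R, "density") == pytest.approx(1.0)

    def test_density_auc_identity(self):
        assert v.auc_over_thresholds(np.eye(4), "density") == 0.0

    def test_density_auc_two_node_half_correlation(self):
        R = np.array([[1.0, 0.5], [0.5, 1.0]])
        # density is 1 up to theta = 0.50, 0 from 0.55 on; trapezoid adds
        # half the 0.05-wide drop interval
        assert v.auc_over_thresholds(R, "density") == pytest.approx(0.525)

    def test_rejects_short_grid(self):
        with pytest.raises(v.ParameterError):
            v.auc_over_thresholds(np.eye(3), "density", np.array([0.5]))

    @pytest.mark.parametrize("seed", range(5))
    def test_density_and_edge_count_non_increasing_in_theta(self, seed):
        rng = np.random.default_rng(seed)
        R = random_correlation_matrix(rng, 10)
        grid = v.DEFAULT_THRESHOLD_GRID
        nets = [v.threshold_network(R, th) for th in grid]
        dens = [v.connection_density(n) for n in nets]
        edges = [n.n_edges for n in nets]
        assert np.all(np.diff(dens) <= 1e-12)
        assert np.all(np.diff(edges) <= 0)

    def test_measures_invariant_under_channel_permutation(self):
        rng = np.random.default_rng(11)
        R = random_correlation_matrix(rng, 8)
        perm = rng.permutation(8)
        Rp = R[np.ix_(perm, perm)]
        for measure in ("density", "avg_clustering"):
            assert v.auc_over_thresholds(R, measure) == pytest.approx(
                v.auc_over_thresholds(Rp, measure), abs=1e-12
            )
        net, netp = v.threshold_network(R, 0.4), v.threshold_network(Rp, 0.4)
        np.testing.assert_allclose(
            np.sort(v.node_strength(net)), np.sort(v.node_strength(netp)), atol=1e-12
        )


class TestHubs:
    def test_star_center_is_the_hub(self):
        R = np.eye(4)
        R[0, 1:] = R[1:, 0] = 0.5
        assert v.hub_nodes(v.threshold_network(R, 0.1)) == {0}

    def test_uniform_triangle_has_no_hubs_under_strict_inequality(self):
        assert v.hub_nodes(triangle(0.5)) == set()

    def test_empty_graph_has_no_hubs(self):
        assert v.hub_nodes(net_from_offdiag([0, 0, 0], 0.5)) == set()
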