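"""Synthetic-data generator: network, covariance, sampling, outcome model."""

import networkx as nx
import numpy as np
import pytest

from fdnn import (
    OutcomeModel,
    SimulationConfig,
    distance_to_covariance,
    generate_dataset,
    generate_labels,
    generate_scale_free_network,
    sample_coefficients,
    sample_gaussian,
    select_true_predictors,
    shortest_path_distances,
)
from fdnn.synthetic import FeatureNetwork


def _bfs_distances(graph, source):
    """Brute-force BFS oracle, independent of the shortest-path implementation."""
    dist = {source: 0}
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for v in graph.neighbors(u):
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


class TestNetwork:
    def test_tree_arity_gives_p_minus_one_edges(self):
        net = generate_scale_free_network(p=3, attach_m=1, seed=0)
        assert len(net.edges) == 2
        net = generate_scale_free_network(p=5000, attach_m=1, seed=1)
        assert len(net.edges) == 4999
        assert nx.is_connected(net.graph)

    def test_degree_distribution_is_heavy_tailed(self):
        net = generate_scale_free_network(p=200, attach_m=2, seed=7)
        degrees = net.degrees()
        assert degrees.max() > 4 * np.median(degrees)

    def test_reproducible_for_fixed_seed(self):
        a = generate_scale_free_network(p=100, attach_m=1, seed=5)
        b = generate_scale_free_network(p=100, attach_m=1, seed=5)
        assert sorted(a.edges) == sorted(b.edges)

    @pytest.mark.parametrize("p,m", [(1, 1), (3, 0), (2, 2)])
    def test_invalid_sizes_rejected(self, p, m):
        with pytest.raises(ValueError):
            generate_scale_free_network(p=p, attach_m=m)


class TestDistances:
    def test_path_and_star_graphs(self):
        path = FeatureNetwork(3, nx.path_graph(3))
        D = shortest_path_distances(path)
        assert D[0, 2] == 2 and D[0, 1] == 1 and D[1, 1] == 0
        star = FeatureNetwork(4, nx.star_graph(3))
        D = shortest_path_distances(star)
        assert D[1, 2] == 2  # leaf to leaf through the center

    def test_agrees_with_bfs_oracle_on_random_tree(self):
        graph = nx.random_labeled_tree(50, seed=3)
        net = FeatureNetwork(50, graph)
        D = shortest_path_distances(net)
        for source in range(50):
            oracle = _bfs_distances(graph, source)
            for target, d in oracle.items():
                assert D[source, target] == d
        assert np.allclose(D, D.T)
        assert np.all(np.diag(D) == 0)

    def test_disconnected_graph_raises(self):
        graph = nx.Graph()
        graph.add_edge(0, 1)
        graph.add_edge(2, 3)
        with pytest.raises(ValueError, match="disconnected"):
            shortest_path_distances(FeatureNetwork(4, graph))


class TestCovariance:
    def test_decay_powers(self):
        D = np.array([[0, 1, 3], [1, 0, 2], [3, 2, 0]], dtype=float)
        sigma, repaired = distance_to_covariance(D, decay=0.7)
        assert sigma[0, 0] == 1.0
        assert sigma[0, 1] == pytest.approx(0.7)
        assert sigma[0, 2] == pytest.approx(0.343)
        assert np.allclose(sigma, sigma.T)

    def test_tree_metric_covariance_is_pd_without_repair(self):
        net = generate_scale_free_network(p=200, attach_m=1, seed=2)
        D = shortest_path_distances(net)
        sigma, repaired = distance_to_covariance(D)
        assert not repaired
        assert np.linalg.eigvalsh(sigma).min() > 0

    def test_repair_restores_unit_diagonal_and_pd(self):
        # a distance-like matrix engineered to break positive definiteness
        D = np.array(
            [[0, 1, 1, 1], [1, 0, 5, 5], [1, 5, 0, 5], [1, 5, 5, 0]], dtype=float
        )
        sigma, _ = distance_to_covariance(D, decay=0.99)
        assert np.allclose(np.diag(sigma), 1.0)
        assert np.linalg.eigvalsh(sigma).min() > 0

    @pytest.mark.parametrize("decay", [0.0, 1.0, -0.5, 1.5])
    def test_invalid_decay_rejected(self, decay):
        with pytest.raises(ValueError):
            distance_to_covariance(np.zeros((2, 2)), decay=decay)


class TestGaussianSampling:
    def test_identity_covariance_moments(self):
        X = sample_gaussian(np.eye(2), n=10000, seed=0)
        assert np.abs(X.mean(axis=0)).max() < 4 / np.sqrt(10000)
        corr = np.corrcoef(X.T)[0, 1]
        assert abs(corr) < 0.05

    def test_correlated_columns(self):
        sigma = np.array([[1.0, 0.7], [0.7, 1.0]])
        X = sample_gaussian(sigma, n=10000, seed=1)
        assert 0.65 <= np.corrcoef(X.T)[0, 1] <= 0.75

    def test_empirical_covariance_converges_entrywise(self):
        net = generate_scale_free_network(p=20, attach_m=1, seed=4)
        sigma, _ = distance_to_covariance(shortest_path_distances(net))
        X = sample_gaussian(sigma, n=20000, seed=4)
        emp = np.cov(X.T)
        assert np.abs(emp - sigma).max() < 0.05

    def test_zero_samples_rejected(self):
        with pytest.raises(ValueError):
            sample_gaussian(np.eye(2), n=0)


class TestPredictorSelection:
    def test_star_graph_single_core(self):
        net = FeatureNetwork(5, nx.star_graph(4))
        idx = select_true_predictors(net, num_cores=1, target_p0=3, seed=0)
        assert 0 in idx  # the hub
        assert len(idx) == 3

    def test_clustered_predictors_within_one_hop(self):
        net = generate_scale_free_network(p=500, attach_m=1, seed=9)
        idx = select_true_predictors(net, num_cores=1, target_p0=10, seed=9)
        degrees = net.degrees()
        core = idx[np.argmax(degrees[idx])]
        for i in idx:
            assert nx.shortest_path_length(net.graph, int(core), int(i)) <= 2

    def test_scattered_half_uniform(self):
        net = generate_scale_free_network(p=1000, attach_m=1, seed=3)
        idx = select_true_predictors(
            net, num_cores=5, target_p0=50, case="scattered", seed=3
        )
        assert len(idx) == 50
        assert len(set(idx.tolist())) == 50

    def test_insufficient_neighborhood_raises(self):
        net = FeatureNetwork(8, nx.path_graph(8))
        with pytest.raises(ValueError, match="num_cores"):
            select_true_predictors(net, num_cores=1, target_p0=7, seed=0)

    def test_clustered_predictors_more_correlated_than_random(self):
        """Selected predictors sit close in the network, so their pairwise
        covariance exceeds that of a random feature subset in most trials."""
        wins = 0
        for seed in range(20):
            net = generate_scale_free_network(p=300, attach_m=1, seed=seed)
            sigma, _ = distance_to_covariance(shortest_path_distances(net))
            idx = select_true_predictors(net, num_cores=2, target_p0=15, seed=seed)
            rng = np.random.default_rng(seed + 1000)
            rand = rng.choice(300, size=15, replace=False)

            def mean_offdiag(s):
                block = sigma[np.ix_(s, s)]
                return (block.sum() - len(s)) / (len(s) * (len(s) - 1))

            if mean_offdiag(idx) > mean_offdiag(rand):
                wins += 1
        assert wins > 10


class TestCoefficientsAndLabels:
    def test_magnitudes_in_range(self):
        beta, b0 = sample_coefficients(50, (0.05, 0.1), 0.5, seed=0)
        assert np.all((np.abs(beta) > 0.05) & (np.abs(beta) < 0.1))
        assert b0 == 0.0

    @pytest.mark.parametrize("frac,sign", [(0.0, 1), (1.0, -1)])
    def test_sign_extremes(self, frac, sign):
        beta, _ = sample_coefficients(30, (0.05, 0.1), frac, seed=1)
        assert np.all(np.sign(beta) == sign)

    def test_labels_match_hand_computed_inverse_logit(self):
        X = np.array([[2.0], [-2.0], [0.0], [0.5], [-0.5]])
        model = OutcomeModel(
            true_predictor_indices=[0],
            coefficients=[1.0],
            intercept=0.0,
            threshold=0.5,
            case="clustered",
        )
        # expit(2)=.881, expit(-2)=.119, expit(0)=.5 (strict >, so 0),
        # expit(.5)=.622, expit(-.5)=.378
        assert generate_labels(X, model).tolist() == [1, 0, 0, 1, 0]

    def test_labels_deterministic(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((50, 10))
        model = OutcomeModel(
            true_predictor_indices=np.arange(5),
            coefficients=rng.uniform(0.05, 0.1, 5),
            intercept=0.0,
            threshold=0.4,
            case="clustered",
        )
        assert np.array_equal(generate_labels(X, model), generate_labels(X, model))

    def test_out_of_range_index_raises(self):
        model = OutcomeModel([10], [0.1], 0.0, 0.5, "clustered")
        with pytest.raises(IndexError):
            generate_labels(np.zeros((3, 5)), model)


class TestGenerateDataset:
    def test_shapes_and_balance(self, small_clustered):
        dataset, outcome, network = small_clustered
        assert dataset.X.shape == (150, 300)
        assert dataset.both_classes_present()
        assert len(outcome.true_predictor_indices) == 20
        assert network.covariance.shape == (300, 300)
        # median threshold yields near-balanced classes
        assert 0.35 <= dataset.y.mean() <= 0.65

    def test_same_seed_is_byte_identical(self):
        cfg = SimulationConfig(p=80, n=40, p0=6, num_cores=1)
        d1, _, _ = generate_dataset(cfg, seed=7)
        d2, _, _ = generate_dataset(cfg, seed=7)
        assert np.array_equal(d1.X, d2.X)
        assert np.array_equal(d1.y, d2.y)

    def test_different_seeds_differ(self):
        cfg = SimulationConfig(p=80, n=40, p0=6, num_cores=1)
        d1, _, _ = generate_dataset(cfg, seed=1)
        d2, _, _ = generate_dataset(cfg, seed=2)
        assert not np.array_equal(d1.X, d2.X)

    def test_provenance_records_parameters(self, small_clustered):
        dataset, _, _ = small_clustered
        assert dataset.provenance["p"] == 300
        assert dataset.provenance["seed"] == 11
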