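"""Graph metrics against closed forms, brute-force oracles, and invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import graph_from
from scnet import reference
from scnet.covariance import BinaryGraph, CovarianceMatrix
from scnet.experiments import random_binary_graph
from scnet.graphmetrics import (
    assortativity,
    characteristic_path_length,
    clustering_coefficient,
    eigenvector_centrality,
    global_efficiency,
    hub_profile,
    random_reference,
    small_worldness,
)


class TestClosedForms:
    def test_k4_clustering(self, k4):
        per_node, mean = clustering_coefficient(k4)
        np.testing.assert_allclose(per_node, 1.0)
        assert mean == 1.0

    def test_star_clustering_zero(self, star4):
        per_node, mean = clustering_coefficient(star4)
        np.testing.assert_allclose(per_node, 0.0)
        assert mean == 0.0

    def test_k4_minus_edge_clustering(self):
        a = 1 - np.eye(4, dtype=int)
        a[0, 1] = a[1, 0] = 0
        per_node, mean = clustering_coefficient(graph_from(a))
        np.testing.assert_allclose(sorted(per_node), [2 / 3, 2 / 3, 1.0, 1.0])
        assert mean == pytest.approx(5 / 6)

    def test_complete_graph_path_length_one(self, k4):
        length, disconnected = characteristic_path_length(k4)
        assert length == 1.0 and not disconnected

    def test_p3_path_length(self, p3):
        length, _ = characteristic_path_length(p3)
        assert length == pytest.approx(4 / 3)

    def test_disjoint_edges_flagged(self):
        a = np.zeros((4, 4), dtype=int)
        a[0, 1] = a[1, 0] = a[2, 3] = a[3, 2] = 1
        length, disconnected = characteristic_path_length(graph_from(a))
        assert length == 1.0 and disconnected

    def test_efficiency_variants_on_p3(self, p3):
        assert global_efficiency(p3) == pytest.approx(0.75)
        assert global_efficiency(p3, "latora_marchiori") == pytest.approx(5 / 6)

    def test_star_eigenvector(self, star4):
        vec = eigenvector_centrality(star4)
        np.testing.assert_allclose(vec, [0.70710678, 0.40824829, 0.40824829, 0.40824829])
        assert vec[0] / vec[1] == pytest.approx(np.sqrt(3))

    def test_p3_eigenvector(self, p3):
        np.testing.assert_allclose(
            eigenvector_centrality(p3), [0.5, 0.70710678, 0.5], atol=1e-8
        )

    def test_k4_eigenvector_uniform(self, k4):
        np.testing.assert_allclose(eigenvector_centrality(k4), 0.5)

    def test_edgeless_graph_rejected(self):
        graph = graph_from(np.zeros((3, 3), dtype=int))
        with pytest.raises(ValueError):
            characteristic_path_length(graph)
        with pytest.raises(ValueError):
            eigenvector_centrality(graph)


class TestAssortativity:
    def test_disjoint_equal_strength_edges(self):
        a = np.zeros((4, 4), dtype=int)
        a[0, 1] = a[1, 0] = a[2, 3] = a[3, 2] = 1
        r = assortativity(graph_from(a), np.array([0.2, 0.2, 0.9, 0.9]))
        assert r == pytest.approx(1.0)

    def test_p3_with_eigenvector_strengths(self, p3):
        r = assortativity(p3, np.array([0.5, 0.70710678, 0.5]))
        assert r == pytest.approx(-1.0)

    def test_constant_strengths_undefined(self, k4):
        with pytest.raises(ValueError, match="undefined"):
            assortativity(k4, np.ones(4))

    def test_matches_brute_force_with_degree_strengths(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            graph = random_binary_graph(rng)
            strength = graph.degrees.astype(float)
            if np.ptp(strength[np.nonzero(np.triu(graph.adjacency, 1))[0]]) == 0:
                continue
            try:
                fast = assortativity(graph, strength)
            except ValueError:
                continue
            assert fast == pytest.approx(
                reference.assortativity_brute(graph.adjacency, strength), abs=1e-12
            )


class TestOracleEquivalence:
    def test_metrics_match_brute_force_on_random_graphs(self):
        import networkx as nx

        rng = np.random.default_rng(123)
        for _ in range(100):
            graph = random_binary_graph(rng)
            a = graph.adjacency
            per_node, _ = clustering_coefficient(graph)
            np.testing.assert_allclose(
                per_node, reference.clustering_brute(a), atol=1e-9
            )
            length, _ = characteristic_path_length(graph)
            assert length == pytest.approx(reference.path_length_brute(a), abs=1e-9)
            if nx.is_connected(nx.from_numpy_array(a)):
                np.testing.assert_allclose(
                    eigenvector_centrality(graph),
                    reference.eigenvector_brute(a),
                    atol=1e-9,
                )


@settings(max_examples=30, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_permutation_equivariance(seed):
    """Per-node metrics commute with any relabeling of the nodes."""
    rng = np.random.default_rng(seed)
    graph = random_binary_graph(rng, max_nodes=10)
    perm = rng.permutation(graph.n_nodes)
    permuted = graph_from(graph.adjacency[np.ix_(perm, perm)])
    clust, _ = clustering_coefficient(graph)
    clust_p, _ = clustering_coefficient(permuted)
    np.testing.assert_allclose(clust[perm], clust_p, atol=1e-12)
    l1, _ = characteristic_path_length(graph)
    l2, _ = characteristic_path_length(permuted)
    assert l1 == pytest.approx(l2, abs=1e-12)


class TestRandomReference:
    def test_degree_sequence_preserved(self):
        rng = np.random.default_rng(7)
        graph = random_binary_graph(rng, max_nodes=12)
        ref = random_reference(graph, seed=1)
        np.testing.assert_array_equal(
            np.sort(graph.degrees), np.sort(ref.degrees)
        )
        np.testing.assert_array_equal(graph.degrees, ref.degrees)

    def test_complete_graph_unchanged(self, k4):
        with pytest.warns(UserWarning, match="no swappable"):
            ref = random_reference(k4, seed=0)
        np.testing.assert_array_equal(ref.adjacency, k4.adjacency)

    def test_rewiring_destroys_lattice_clustering(self):
        import networkx as nx

        ring = nx.watts_strogatz_graph(40, 6, 0.0, seed=0)  # pure ring lattice
        graph = graph_from(nx.to_numpy_array(ring, dtype=np.int8))
        _, c_lattice = clustering_coefficient(graph)
        rewired_c = [
            clustering_coefficient(random_reference(graph, seed=s))[1]
            for s in range(100)
        ]
        assert np.mean(rewired_c) < c_lattice


class TestSmallWorldness:
    def test_sigma_consistent_with_components(self):
        """sigma equals (C/C_rand)/(L/L_rand) from the reported components,
        and reduces to exactly 1 when the graph is its own reference."""
        import networkx as nx

        g = nx.erdos_renyi_graph(25, 0.25, seed=1)
        graph = graph_from(nx.to_numpy_array(g, dtype=np.int8))
        result = small_worldness(graph, n_rand=5, seed=9)
        expected = (result.clustering / result.clustering_rand) / (
            result.path_length / result.path_length_rand
        )
        assert result.sigma == pytest.approx(expected, abs=1e-12)
        self_sigma = (result.clustering / result.clustering) / (
            result.path_length / result.path_length
        )
        assert self_sigma == 1.0

    def test_returns_components_and_sd(self):
        import networkx as nx

        g = nx.erdos_renyi_graph(30, 0.3, seed=2)
        graph = graph_from(nx.to_numpy_array(g, dtype=np.int8))
        result = small_worldness(graph, n_rand=10, seed=4)
        assert result.clustering_rand > 0
        assert result.sigma_sd >= 0
        assert result.connected


class TestHubProfile:
    def test_z_scores_standardized_and_threshold(self, small_cohort):
        from scnet.covariance import build_covariance
        from scnet.preprocess import mad_rescale, regress_covariates

        _, table = small_cohort
        cov = build_covariance(regress_covariates(mad_rescale(table)), "A")
        with pytest.warns(UserWarning):
            profile = hub_profile(cov, grid=(0.15, 0.35, 0.05))
        assert profile.z_scores.mean() == pytest.approx(0.0, abs=1e-8)
        assert profile.z_scores.std() == pytest.approx(1.0, abs=1e-8)
        np.testing.assert_array_equal(profile.hubs, profile.z_scores > 1.5)

    def test_exchangeable_regions_yield_few_hubs(self):
        """Single-block cohort: no structural hubs, so hub calls are rare."""
        from scnet.covariance import build_covariance
        from scnet.preprocess import regress_covariates
        from scnet.synthetic import SyntheticConfig, generate_cohort

        counts = []
        for seed in range(5):
            config = SyntheticConfig(
                n_regions=30,
                module_labels=np.ones(30, dtype=int),
                per_site_counts={"site01": 100},
                rho_within=0.4,
                rho_between=0.4,
                seed=seed,
            )
            residuals = regress_covariates(generate_cohort(config))
            cov = build_covariance(residuals, "A")
            profile = hub_profile(cov, grid=(0.2, 0.35, 0.05))
            counts.append(profile.hubs.sum())
        assert np.mean(counts) <= 0.1 * 30

    def test_constant_centrality_errors(self):
        values = np.full((4, 4), 0.5)
        np.fill_diagonal(values, 1.0)
        matrix = CovarianceMatrix(values, [f"r{i}" for i in range(4)])
        with pytest.raises(ValueError, match="constant"):
            hub_profile(matrix, grid=(1.0, 1.0, 0.5))
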