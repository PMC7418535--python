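"""Graph metrics against closed forms and exhaustive brute-force oracles."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from olfnet import graphmetrics as gm
from olfnet.containers import BinaryNetwork, Partition

from oracles import (bf_best_modularity, bf_betweenness, bf_closeness,
                     bf_clustering, bf_global_efficiency, bf_modularity,
                     bf_participation, bf_path_length, bf_zrand,
                     random_connected_graph)


def graph_of(adj):
    return nx.from_numpy_array(np.asarray(adj))


class TestClosedForms:
    def test_triangle_clusters_perfectly(self):
        assert gm.clustering_coefficient(graph_of(1 - np.eye(3))) == 1.0

    def test_star_has_zero_clustering(self):
        assert gm.clustering_coefficient(nx.star_graph(5)) == 0.0

    def test_complete_graph_unit_efficiency(self):
        assert gm.global_efficiency(graph_of(1 - np.eye(6))) == pytest.approx(1.0)

    def test_three_node_path_efficiency(self):
        assert gm.global_efficiency(nx.path_graph(3)) == pytest.approx(
            (1 + 1 + 0.5) / 3)

    def test_star_center_centralities(self):
        c = gm.centralities(nx.star_graph(4))
        assert c.loc[0, "betweenness"] == 1.0
        assert c.loc[0, "closeness"] == 1.0
        assert (c.loc[1:, "betweenness"] == 0).all()
        assert c.loc[1, "closeness"] == pytest.approx(4 / 7)

    def test_participation_formula_values(self):
        g = nx.Graph()
        # hub 'h' with degree 4 split 2/2 across two modules
        g.add_edges_from([("h", "a1"), ("h", "a2"), ("h", "b1"), ("h", "b2"),
                          ("a1", "a2"), ("b1", "b2")])
        labels = {"h": 0, "a1": 0, "a2": 0, "b1": 1, "b2": 1}
        p = gm.participation_coefficient(g, labels)
        assert p.loc["h", "participation"] == pytest.approx(0.5)
        # degree 3 split evenly across three modules
        g2 = nx.star_graph(3)
        p2 = gm.participation_coefficient(g2, {0: 0, 1: 1, 2: 2, 3: 3})
        assert p2.loc[0, "participation"] == pytest.approx(1 - 3 / 9)

    def test_within_module_edges_give_zero_participation(self):
        g = graph_of(1 - np.eye(4))
        p = gm.participation_coefficient(g, {n: 0 for n in g.nodes()})
        assert (p["participation"] == 0).all()

    def test_disconnected_cliques_louvain(self):
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        part = gm.modularity_louvain(g, n_restarts=5, seed=0)
        assert part.n_modules == 2
        assert part.q == pytest.approx(0.5)

    def test_complete_graph_single_module(self):
        g = nx.complete_graph(6)
        part = gm.modularity_louvain(g, n_restarts=5, seed=0)
        assert part.n_modules == 1
        assert part.q == pytest.approx(0.0, abs=1e-12)

    def test_star_center_removal_destroys_efficiency(self):
        imp = gm.node_deletion_impact(nx.star_graph(5))
        assert imp.loc[0, "deletion_impact_pct"] == pytest.approx(100.0)

    def test_complete_graph_deletion_impact_zero(self):
        imp = gm.node_deletion_impact(graph_of(1 - np.eye(6)))
        assert np.allclose(imp["deletion_impact_pct"], 0.0)


class TestBruteForceEquivalence:
    """Implementation vs exhaustive enumeration on random small graphs."""

    N_GRAPHS = 100

    def test_metrics_match_oracles_on_random_graphs(self, rng):
        for i in range(self.N_GRAPHS):
            n = int(rng.integers(4, 8))
            adj = random_connected_graph(rng, n, p=float(rng.uniform(0.3, 0.9)))
            g = graph_of(adj)
            labels = rng.integers(0, 3, n)
            assert gm.clustering_coefficient(g) == pytest.approx(
                bf_clustering(adj), abs=1e-10)
            assert gm.global_efficiency(g) == pytest.approx(
                bf_global_efficiency(adj), abs=1e-10)
            assert gm.characteristic_path_length(g) == pytest.approx(
                bf_path_length(adj), abs=1e-10)
            cent = gm.centralities(g)
            assert np.allclose(cent["betweenness"], bf_betweenness(adj),
                               atol=1e-10)
            assert np.allclose(cent["closeness"], bf_closeness(adj),
                               atol=1e-10)
            q = gm.modularity_q(g, {i: int(labels[i]) for i in range(n)})
            assert q == pytest.approx(bf_modularity(adj, labels), abs=1e-10)
            part = gm.participation_coefficient(
                g, {i: int(labels[i]) for i in range(n)})
            assert np.allclose(part["participation"], bf_participation(adj, labels),
                               atol=1e-10)

    def test_louvain_finds_global_optimum_on_small_graphs(self, rng):
        for _ in range(15):
            n = int(rng.integers(5, 8))
            adj = random_connected_graph(rng, n, p=0.5)
            part = gm.modularity_louvain(graph_of(adj), n_restarts=40,
                                         seed=int(rng.integers(2 ** 31 - 1)))
            assert part.q == pytest.approx(bf_best_modularity(adj), abs=1e-9)

    def test_zrand_matches_exhaustive_permutation_moments(self, rng):
        done = 0
        while done < 12:
            a = rng.integers(0, 3, 6)
            b = rng.integers(0, 3, 6)
            try:
                z = gm.zrand_similarity({i: int(x) for i, x in enumerate(a)},
                                        {i: int(x) for i, x in enumerate(b)})
            except ValueError:
                continue
            assert z == pytest.approx(bf_zrand(a, b), abs=1e-10)
            done += 1


class TestCompositeHubness:
    def test_uniform_nodes_have_zero_composite(self):
        g = nx.cycle_graph(6)
        table = gm.composite_hubness(gm.centralities(g))
        assert np.allclose(table["composite_z"], 0.0)

    def test_dominant_node_ranks_first(self):
        g = nx.star_graph(5)
        g.add_edge(1, 2)
        table = gm.composite_hubness(gm.centralities(g))
        assert table["composite_rank"].idxmin() == 0
        assert table["composite_z"].idxmax() == 0

    def test_composite_z_averages_zero_over_nodes(self, rng):
        adj = random_connected_graph(rng, 7, 0.5)
        table = gm.composite_hubness(gm.centralities(graph_of(adj)))
        assert table["composite_z"].mean() == pytest.approx(0.0, abs=1e-12)


class TestModularityAlgorithms:
    def test_q_consistent_with_independent_formula(self, karate):
        part = gm.modularity_louvain(karate, n_restarts=20, seed=1)
        adj = nx.to_numpy_array(karate, weight=None)
        labels = [part.labels[n] for n in karate.nodes()]
        assert part.q == pytest.approx(bf_modularity(adj, labels), abs=1e-12)

    def test_girvan_newman_removes_bridge_first(self):
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        g.add_edge(0, 4)
        part = gm.modularity_girvan_newman(g)
        assert part.n_modules == 2
        assert len({part.labels[n] for n in range(4)}) == 1

    def test_girvan_newman_terminates_on_tree(self):
        part = gm.modularity_girvan_newman(nx.random_labeled_tree(10, seed=3))
        assert part.n_modules >= 1
        assert np.isfinite(part.q)

    def test_girvan_newman_agrees_with_louvain_on_planted_graph(self, planted_runs):
        net = planted_runs[0]["network"]
        q_l = planted_runs[0]["partition"].q
        q_gn = gm.modularity_girvan_newman(net).q
        assert abs(q_l - q_gn) < 0.05

    def test_louvain_deterministic_given_seed(self, karate):
        p1 = gm.modularity_louvain(karate, n_restarts=10, seed=42)
        p2 = gm.modularity_louvain(karate, n_restarts=10, seed=42)
        assert p1.labels == p2.labels and p1.q == p2.q

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            gm.modularity_louvain(nx.empty_graph(4))


class TestNullModels:
    def test_rewiring_preserves_degree_sequence_exactly(self, karate, rng):
        degrees = sorted(d for _, d in karate.degree())
        for _ in range(10):
            h = gm.rewired_null(karate, rng)
            assert sorted(d for _, d in h.degree()) == degrees

    def test_null_operations_seed_deterministic(self, karate):
        a = gm.modularity_zscore(karate, n_perm=20, seed=5, n_restarts=2)
        b = gm.modularity_zscore(karate, n_perm=20, seed=5, n_restarts=2)
        assert np.array_equal(a.q_rand, b.q_rand)

    def test_doubling_permutations_shrinks_standard_error(self, karate):
        means_small, means_big = [], []
        for s in range(12):
            means_small.append(gm.modularity_zscore(
                karate, n_perm=20, seed=s, n_restarts=1).mean)
            means_big.append(gm.modularity_zscore(
                karate, n_perm=80, seed=100 + s, n_restarts=1).mean)
        assert np.std(means_big) < np.std(means_small)

    def test_single_permutation_rejected(self, karate):
        with pytest.raises(ValueError):
            gm.modularity_zscore(karate, n_perm=1, seed=0)

    def test_strongly_modular_net_exceeds_z_cutoff(self):
        g = nx.disjoint_union(nx.complete_graph(6), nx.complete_graph(6))
        g.add_edge(0, 6)
        null = gm.modularity_zscore(g, n_perm=60, seed=2, n_restarts=3)
        assert null.zscore > 3

    def test_erdos_renyi_null_preserves_edge_count_only(self, karate, rng):
        h = gm.rewired_null(karate, rng, null="erdos_renyi")
        assert h.number_of_edges() == karate.number_of_edges()


class TestSmallWorld:
    def test_complete_graph_sigma_one(self):
        sw = gm.small_world(nx.complete_graph(6), n_rand=5, seed=0)
        assert sw.sigma == pytest.approx(1.0)
        assert sw.c == sw.c_rand == 1.0

    def test_disconnected_graph_rejected(self):
        g = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3))
        with pytest.raises(ValueError, match="connected"):
            gm.small_world(g, n_rand=5, seed=0)

    def test_weighted_metrics_reduce_to_binary_at_unit_weights(self, karate):
        for u, v in karate.edges():
            karate[u][v]["weight"] = 1.0
        assert gm.clustering_coefficient(karate, weighted=True) == pytest.approx(
            gm.clustering_coefficient(karate, weighted=False))
        assert gm.global_efficiency(karate, weighted=True) == pytest.approx(
            gm.global_efficiency(karate, weighted=False))

    def test_negative_weights_rejected(self):
        g = nx.Graph()
        g.add_edge(0, 1, weight=-0.5)
        g.add_edge(1, 2, weight=0.5)
        with pytest.raises(ValueError, match="negative"):
            gm.global_efficiency(g, weighted=True)


class TestZrandBehavior:
    def test_identical_nontrivial_partitions_positive(self):
        labels = {i: i % 3 for i in range(12)}
        assert gm.zrand_similarity(labels, dict(labels)) > 0

    def test_independent_partitions_center_on_zero(self, rng):
        zs = []
        for _ in range(400):
            a = {i: int(x) for i, x in enumerate(rng.integers(0, 3, 22))}
            b = {i: int(x) for i, x in enumerate(rng.integers(0, 3, 22))}
            try:
                zs.append(gm.zrand_similarity(a, b))
            except ValueError:
                continue
        assert abs(np.mean(zs)) < 0.1

    def test_single_module_partition_degenerate(self):
        a = {i: 0 for i in range(8)}
        b = {i: i % 2 for i in range(8)}
        with pytest.raises(ValueError, match="degenerate"):
            gm.zrand_similarity(a, b)

    def test_mismatched_node_sets_rejected(self):
        with pytest.raises(ValueError):
            gm.zrand_similarity({1: 0, 2: 1}, {1: 0, 3: 1})


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_participation_bounded_on_random_graphs(seed):
    rng = np.random.default_rng(seed)
    adj = random_connected_graph(rng, int(rng.integers(4, 9)), 0.5)
    g = graph_of(adj)
    labels = {i: int(x) for i, x in enumerate(rng.integers(0, 4, adj.shape[0]))}
    p = gm.participation_coefficient(g, labels)["participation"]
    assert ((p >= 0) & (p <= 1)).all()


def test_node_metrics_table_contains_all_quantities(planted_runs):
    run = planted_runs[0]
    table = gm.node_metrics(run["network"], run["partition"])
    for col in ("degree", "betweenness", "closeness", "composite_z",
                "composite_rank", "participation", "deletion_impact_pct"):
        assert col in table.columns
    assert ((table["participation"] >= 0) & (table["participation"] <= 1)).all()
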