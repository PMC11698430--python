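"""Evaluation measures: rank correlation, overlap, edge and graph
properties, KS statistic — each against a printed value or brute force."""

import math

import networkx as nx
import numpy as np
import pytest

from netbackbone import metrics
from netbackbone.graph import WeightedNetwork
from netbackbone.synth import fixture

from conftest import random_network


class TestSpearman:
    def test_perfect_reversal(self):
        assert metrics.spearman([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_identity(self):
        assert metrics.spearman([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_tie_handling_matches_hand_ranks(self):
        # ranks of (1,2,2) are (1, 2.5, 2.5); Pearson vs (1,2,3) ranks
        r = metrics.spearman([1, 2, 2], [1, 2, 3])
        ranks_x = np.array([1.0, 2.5, 2.5])
        ranks_y = np.array([1.0, 2.0, 3.0])
        expected = np.corrcoef(ranks_x, ranks_y)[0, 1]
        assert r == pytest.approx(expected)
        assert r == pytest.approx(0.866, abs=1e-3)

    def test_constant_input_is_missing(self):
        assert math.isnan(metrics.spearman([1, 1, 1], [1, 2, 3]))

    def test_symmetric_and_monotone_invariant(self):
        rng = np.random.default_rng(0)
        x = rng.random(50)
        y = rng.random(50)
        assert metrics.spearman(x, y) == pytest.approx(metrics.spearman(y, x))
        assert metrics.spearman(np.exp(3 * x), y) == pytest.approx(
            metrics.spearman(x, y)
        )


class TestOverlap:
    def test_half_overlap(self):
        assert metrics.overlap_from({"ab", "bc"}, {"bc", "cd"}) == 0.5

    def test_containment_gives_one(self):
        assert metrics.overlap_from({"ab"}, {"ab", "bc", "cd"}) == 1.0

    def test_disjoint_gives_zero(self):
        assert metrics.overlap_from({"ab"}, {"cd"}) == 0.0

    def test_empty_reference_is_missing(self):
        assert math.isnan(metrics.overlap_from(set(), {"ab"}))

    @pytest.mark.parametrize("seed", range(10))
    def test_intersection_identity(self, seed):
        rng = np.random.default_rng(seed)
        X = set(map(int, rng.integers(0, 30, 12)))
        Y = set(map(int, rng.integers(0, 30, 12)))
        if not X or not Y:
            return
        assert metrics.overlap_from(X, Y) * len(X) == pytest.approx(
            len(X & Y)
        )
        assert metrics.overlap_from(Y, X) * len(Y) == pytest.approx(
            len(X & Y)
        )


class TestEdgeProperties:
    def test_edge_degree_path(self, path3):
        kd = metrics.edge_degree(path3)
        assert kd[("a", "b")] == 2  # 1 * 2

    def test_edge_degree_star_and_triangle(self, star5, triangle):
        assert all(v == 5 for v in metrics.edge_degree(star5).values())
        assert all(v == 4 for v in metrics.edge_degree(triangle).values())

    def test_betweenness_path(self, path3):
        b = metrics.edge_betweenness(path3)
        assert b[("a", "b")] == pytest.approx(2.0)  # pairs {a,b}, {a,c}

    def test_betweenness_triangle(self, triangle):
        b = metrics.edge_betweenness(triangle)
        assert all(v == pytest.approx(1.0) for v in b.values())

    def test_betweenness_disconnected_components_independent(self):
        net = WeightedNetwork.from_edges(
            [("a", "b", 1), ("c", "d", 1), ("d", "e", 1)]
        )
        b = metrics.edge_betweenness(net)
        assert b[("a", "b")] == pytest.approx(1.0)
        assert b[("c", "d")] == pytest.approx(2.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_tree_betweenness_sums_to_pair_distances(self, seed):
        # with unique shortest paths, sum_e b(e) = sum of pairwise
        # distances
        tree = nx.random_labeled_tree(12, seed=seed)
        nx.set_edge_attributes(tree, 1.0, "weight")
        net = WeightedNetwork(tree)
        total_b = sum(metrics.edge_betweenness(net).values())
        dist_sum = sum(
            d
            for u, lengths in dict(
                nx.all_pairs_shortest_path_length(tree)
            ).items()
            for v, d in lengths.items()
        ) / 2
        assert total_b == pytest.approx(dist_sum)


class TestGraphProperties:
    def test_entropy_uniform_four_edges(self):
        net = WeightedNetwork.from_edges(
            [("a", "b", 3), ("b", "c", 3), ("c", "d", 3), ("d", "a", 3)]
        )
        assert metrics.weight_entropy(net) == pytest.approx(2.0)

    def test_entropy_single_edge_zero(self):
        net = WeightedNetwork.from_edges([("a", "b", 5)])
        assert metrics.weight_entropy(net) == pytest.approx(0.0)

    def test_entropy_weighted_shares(self):
        net = WeightedNetwork.from_edges(
            [("a", "b", 1), ("b", "c", 1), ("c", "d", 2)]
        )
        assert metrics.weight_entropy(net) == pytest.approx(1.5)

    def test_reachability_connected(self, triangle):
        assert metrics.reachability(triangle) == 1.0

    def test_reachability_two_dyads(self):
        net = WeightedNetwork.from_edges([("a", "b", 1), ("c", "d", 1)])
        assert metrics.reachability(net) == pytest.approx(1 / 3)

    def test_reachability_two_cliques_without_bridge(self, two_cliques):
        g = two_cliques.graph.copy()
        g.remove_edge("l0", "r0")
        assert metrics.reachability(g) == pytest.approx(3 / 7)

    def test_transitivity_cases(self, triangle, path3):
        assert metrics.transitivity(triangle) == 1.0
        assert metrics.transitivity(path3) == 0.0
        cycle4 = WeightedNetwork.from_edges(
            [("a", "b", 1), ("b", "c", 1), ("c", "d", 1), ("d", "a", 1)]
        )
        assert metrics.transitivity(cycle4) == 0.0


class TestKS:
    def test_identical_samples(self):
        assert metrics.ks_statistic([1, 2, 3], [1, 2, 3]) == 0.0

    def test_disjoint_supports(self):
        assert metrics.ks_statistic([0, 0], [1, 1]) == 1.0

    def test_stepwise_example(self):
        assert metrics.ks_statistic([1, 2], [1, 3]) == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_ecdf_scan(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 20, rng.integers(2, 200)).astype(float)
        b = rng.integers(0, 20, rng.integers(2, 200)).astype(float)
        pooled = np.concatenate([a, b])
        d_brute = max(
            abs((a <= x).mean() - (b <= x).mean()) for x in pooled
        )
        assert metrics.ks_statistic(a, b) == pytest.approx(d_brute)
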