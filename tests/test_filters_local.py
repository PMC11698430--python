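"""Disparity and LANS filters: closed forms, counting rules, invariants."""

import numpy as np
import pytest
from scipy.integrate import quad

from netbackbone.graph import WeightedNetwork
from netbackbone.filters import disparity_pvalues, lans_pvalues

from conftest import random_network


def uniform_split_survival(w_over_s: float, k: int) -> float:
    """Independent oracle: survival of one normalized weight when a node
    splits unit strength uniformly among k edges — numeric integration of
    the order-statistic density (k-1)(1-x)^(k-2)."""
    cdf, _ = quad(lambda x: (k - 1) * (1 - x) ** (k - 2), 0.0, w_over_s)
    return 1.0 - cdf


class TestDisparity:
    def test_matches_numeric_integration(self):
        # node i: k=3, s=10, w=5 -> one-sided p = (1 - 0.5)^2 = 0.25
        net = WeightedNetwork.from_edges(
            [("i", "a", 5), ("i", "b", 3), ("i", "c", 2), ("a", "b", 1)]
        )
        pv = disparity_pvalues(net)
        p_i = pv.side[("a", "i")][1]  # endpoint i of edge (a, i)
        assert p_i == pytest.approx(0.25, abs=1e-12)
        assert p_i == pytest.approx(uniform_split_survival(0.5, 3), abs=1e-10)

    @pytest.mark.parametrize("k,w_frac", [(2, 0.3), (4, 0.1), (6, 0.55)])
    def test_closed_form_equals_integral_oracle(self, k, w_frac):
        closed = (1 - w_frac) ** (k - 1)
        assert closed == pytest.approx(
            uniform_split_survival(w_frac, k), abs=1e-10
        )

    def test_equal_weights_give_half_at_degree_two(self, path3):
        pv = disparity_pvalues(path3)
        # center node b has k=2, both edges carry half its strength
        assert pv.side[("a", "b")][1] == pytest.approx(0.5)
        assert pv.side[("b", "c")][0] == pytest.approx(0.5)

    def test_degree_one_endpoints_give_p_one(self):
        net = WeightedNetwork.from_edges([("a", "b", 7)])
        pv = disparity_pvalues(net)
        assert pv.p[("a", "b")] == 1.0

    def test_star_hub_survival(self, star5):
        pv = disparity_pvalues(star5)
        # hub strength 31; heaviest leaf edge w=16
        assert pv.side[("hub", "leaf4")][0] == pytest.approx(
            (1 - 16 / 31) ** 4
        )

    def test_edge_p_is_min_of_sides(self, het100):
        pv = disparity_pvalues(het100)
        for e, (pu, pvv) in pv.side.items():
            assert pv.p[e] == min(pu, pvv)


class TestLans:
    def test_strict_counting(self):
        net = WeightedNetwork.from_edges(
            [("i", "a", 1), ("i", "b", 2), ("i", "c", 3), ("a", "b", 10)]
        )
        pv = lans_pvalues(net)
        # from node i: weights {1,2,3}; w=3 -> 0 heavier; w=1 -> 2/3
        assert pv.side[("c", "i")][1] == 0.0
        assert pv.side[("a", "i")][1] == pytest.approx(2 / 3)

    def test_ties_score_zero(self):
        net = WeightedNetwork.from_edges([("i", "a", 2), ("i", "b", 2)])
        pv = lans_pvalues(net)
        assert pv.side[("a", "i")][1] == 0.0
        assert pv.side[("b", "i")][1] == 0.0

    def test_degree_one_node_scores_zero(self):
        net = WeightedNetwork.from_edges([("a", "b", 1), ("b", "c", 9)])
        pv = lans_pvalues(net)
        # leaf a has no heavier incident edge, so its side is 0 and the
        # edge survives any positive significance level
        assert pv.p[("a", "b")] == 0.0

    def test_inclusive_counting_would_kill_top_edges(self, star5):
        # contrast: with >= counting every hub edge would score >= 1/k;
        # the implemented strict counting keeps each node's strongest edge
        pv = lans_pvalues(star5)
        assert pv.p[("hub", "leaf4")] == 0.0
        inclusive = {
            e: sum(
                1
                for w2 in star5.incident_weights("hub")
                if w2 >= star5.weight(*e)
            )
            / star5.degree("hub")
            for e in star5.edge_set()
        }
        assert inclusive[("hub", "leaf4")] == pytest.approx(1 / 5)


class TestSharedInvariants:
    @pytest.mark.parametrize("seed", range(15))
    def test_pvalues_in_unit_interval(self, seed):
        net = random_network(seed)
        for fn in (disparity_pvalues, lans_pvalues):
            pv = fn(net)
            assert set(pv.p) == set(net.edge_set())
            assert all(0.0 <= p <= 1.0 for p in pv.p.values())

    def test_monotone_in_weight_for_fixed_node(self):
        # one hub, distinct weights: heavier edge never has larger
        # one-sided p from the hub's viewpoint
        net = WeightedNetwork.from_edges(
            [("h", f"x{i}", w) for i, w in enumerate([1, 2, 4, 9, 20])]
        )
        for fn in (disparity_pvalues, lans_pvalues):
            pv = fn(net)
            sides = [
                pv.side[e][0] if e[0] == "h" else pv.side[e][1]
                for e in sorted(
                    net.edge_set(), key=lambda e: net.weight(*e)
                )
            ]
            assert all(a >= b for a, b in zip(sides, sides[1:]))

    def test_endpoint_relabeling_invariance(self, seed=3):
        net = random_network(seed)
        relabeled = WeightedNetwork.from_edges(
            [(v, u, w) for u, v, w in net.edges()]
        )
        for fn in (disparity_pvalues, lans_pvalues):
            assert fn(net).p == fn(relabeled).p
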