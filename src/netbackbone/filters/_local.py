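"""Per-endpoint filters built on each node's own incident weights.

Disparity filter (DF): under the null, a node of degree k splits its
strength s uniformly at random among its k edges, so each normalized weight
w/s is distributed like the minimum-spacing order statistic of k-1 uniform
points; the one-sided survival probability is (1 - w/s)**(k-1).

LANS: no distributional assumption at all — a node scores each incident
edge by the fraction of its own incident edges that are strictly heavier.

Both take the minimum of the two endpoint p-values as the edge p-value.
"""

from __future__ import annotations

from ..graph import WeightedNetwork, edge_key
from ._base import EdgePValues

__all__ = ["disparity_pvalues", "lans_pvalues"]


def _one_sided_disparity(w: float, s: float, k: int) -> float:
    # degree-1 nodes have a degenerate null (their single edge carries all
    # of s); they contribute the non-informative p = 1
    if k <= 1:
        return 1.0
    x = min(w / s, 1.0)
    return (1.0 - x) ** (k - 1)


def disparity_pvalues(net: WeightedNetwork) -> EdgePValues:
    """Disparity-filter p-values: uniform split of node strength.

    The one-sided p-value seen from endpoint i is
    ``p_i = (1 - w/s_i)**(k_i - 1)`` (p = 1 when ``k_i = 1``); the edge
    p-value is the minimum over the two endpoints.
    """
    p: dict[tuple[str, str], float] = {}
    side: dict[tuple[str, str], tuple[float, float]] = {}
    for u, v, w in net.edges():
        pu = _one_sided_disparity(w, net.strength(u), net.degree(u))
        pv = _one_sided_disparity(w, net.strength(v), net.degree(v))
        e = edge_key(u, v)
        side[e] = (pu, pv)
        p[e] = min(pu, pv)
    return EdgePValues(net=net, method="df", p=p, side=side)


def lans_pvalues(net: WeightedNetwork) -> EdgePValues:
    """Locally adaptive network sparsification p-values.

    The one-sided p-value from endpoint i is the fraction of i's incident
    edges strictly heavier than the edge under test; the edge p-value is
    the minimum over the two endpoints.  Strict counting means every
    node's heaviest incident edge scores p = 0, so no node can lose all of
    its edges at any positive significance level.
    """
    # per-node sorted incident weights for O(deg log deg) survival counting
    heavier: dict[str, list[float]] = {
        n: sorted(net.incident_weights(n)) for n in net.nodes
    }

    def one_sided(n: str, w: float) -> float:
        ws = heavier[n]
        # count strictly greater via binary search from the right
        import bisect

        cnt = len(ws) - bisect.bisect_right(ws, w)
        return cnt / len(ws)

    p: dict[tuple[str, str], float] = {}
    side: dict[tuple[str, str], tuple[float, float]] = {}
    for u, v, w in net.edges():
        pu = one_sided(u, w)
        pv = one_sided(v, w)
        e = edge_key(u, v)
        side[e] = (pu, pv)
        p[e] = min(pu, pv)
    return EdgePValues(net=net, method="lans", p=p, side=side)
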