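"""Pólya-urn filter: beta-binomial null for a node's weight allocation.

From the viewpoint of endpoint i with degree k and strength s, the null
assumes the node distributed its s unit weight packets one at a time over
its k edges by a Pólya urn with reinforcement parameter a: each packet
lands on an edge with probability proportional to (current weight on that
edge)·a + 1.  The resulting weight of one edge is beta-binomial,

    W ~ BetaBinomial(n = s, alpha = 1/a, beta = (k - 1)/a),

and the one-sided p-value is the survival P(W >= w).  As a -> 0 the urn
loses memory and W -> Binomial(s, 1/k); at a = 1 and large s the law of
W/s approaches the disparity filter's uniform-split null.  The edge
p-value is the minimum over the two endpoints.
"""

from __future__ import annotations

import numpy as np
from scipy.special import betaln, gammaln, logsumexp

from ..graph import WeightedNetwork, edge_key
from ._base import EdgePValues, FilterError

__all__ = ["polya_pvalues", "beta_binomial_survival"]


def _beta_binomial_logpmf(x: np.ndarray, n: int, a: float, b: float) -> np.ndarray:
    return (
        gammaln(n + 1)
        - gammaln(x + 1)
        - gammaln(n - x + 1)
        + betaln(x + a, n - x + b)
        - betaln(a, b)
    )


def beta_binomial_survival(w: int, n: int, alpha: float, beta: float) -> float:
    """P(W >= w) for W ~ BetaBinomial(n, alpha, beta), in log space."""
    if w <= 0:
        return 1.0
    if w > n:
        return 0.0
    x = np.arange(w, n + 1, dtype=float)
    return float(min(1.0, np.exp(logsumexp(_beta_binomial_logpmf(x, n, alpha, beta)))))


def polya_pvalues(net: WeightedNetwork, a: float = 1.0) -> EdgePValues:
    """Pólya-urn-filter p-values with reinforcement parameter ``a``.

    Endpoints of degree 1 have a degenerate null (all of s lands on the
    single edge) and contribute p = 1, mirroring the disparity filter.
    """
    if a <= 0:
        raise ValueError(f"reinforcement parameter a must be > 0, got {a}")
    if not net.has_integer_weights:
        raise FilterError(
            "pf requires integer weights; run graph.validate_for_method "
            "for scale-and-round guidance"
        )

    # per-node survival table: one beta-binomial tail vector per node
    # serves all its incident edges
    tails: dict[str, np.ndarray] = {}
    for n in net.nodes:
        k = net.degree(n)
        if k <= 1:
            continue
        s = int(round(net.strength(n)))
        logpmf = _beta_binomial_logpmf(
            np.arange(s + 1, dtype=float), s, 1.0 / a, (k - 1) / a
        )
        pmf = np.exp(logpmf)
        # reverse cumulative sum: tail[w] = P(W >= w)
        tail = np.cumsum(pmf[::-1])[::-1]
        tails[n] = np.minimum(tail, 1.0)

    def one_sided(node: str, w: float) -> float:
        if net.degree(node) <= 1:
            return 1.0
        return float(tails[node][int(round(w))])

    p: dict[tuple[str, str], float] = {}
    side: dict[tuple[str, str], tuple[float, float]] = {}
    for u, v, w in net.edges():
        pu = one_sided(u, w)
        pv = one_sided(v, w)
        e = edge_key(u, v)
        side[e] = (pu, pv)
        p[e] = min(pu, pv)
    return EdgePValues(net=net, method="pf", p=p, side=side, params={"a": a})
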