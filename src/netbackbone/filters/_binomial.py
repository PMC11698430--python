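"""Binomial null models: marginal-likelihood (MLF) and noise-corrected (NC).

Both model an integer edge weight as a count of unit weight packets placed
independently between node pairs with probability proportional to the
product of endpoint strengths; they differ in the trial convention:

* MLF: ``W ~ Binomial(n = T, q = s_i s_j / (2 T^2))`` — T trials, one per
  unit of total weight.
* NC:  ``W ~ Binomial(n = N_t, q = s_i s_j / N_t^2)`` with ``N_t = 2T``.

Both share the null mean ``s_i s_j / N_t`` and conserve expected total
weight; NC halves the per-trial success probability while doubling the
trial count, giving a slightly different variance.  The edge p-value is the
symmetric survival ``P(W >= w)``, computed through the regularized
incomplete beta function.
"""

from __future__ import annotations

import logging

from scipy import stats

from ..graph import WeightedNetwork, edge_key
from ._base import EdgePValues, FilterError

logger = logging.getLogger(__name__)

__all__ = ["mlf_pvalues", "nc_pvalues"]


def _require_integer(net: WeightedNetwork, method: str) -> None:
    if not net.has_integer_weights:
        raise FilterError(
            f"{method} requires integer weights; run "
            "graph.validate_for_method for scale-and-round guidance"
        )


def _binomial_survival(w: float, n: int, q: float) -> float:
    # P(X >= w) for X ~ Bin(n, q); sf(w-1) is the regularized incomplete
    # beta tail, accurate in the far tail without explicit summation
    if w <= 0:
        return 1.0
    return float(stats.binom.sf(w - 1, n, q))


def mlf_pvalues(net: WeightedNetwork) -> EdgePValues:
    """Marginal-likelihood-filter p-values (binomial null with n = T)."""
    _require_integer(net, "mlf")
    T = int(round(net.total_weight))
    if T < 1:
        raise FilterError("mlf requires total weight >= 1")
    p: dict[tuple[str, str], float] = {}
    for u, v, w in net.edges():
        q = net.strength(u) * net.strength(v) / (2.0 * T * T)
        if q > 1.0:
            logger.warning(
                "mlf: q_ij = %.3g > 1 for edge (%s, %s); clipping", q, u, v
            )
            q = 1.0
        p[edge_key(u, v)] = _binomial_survival(w, T, q)
    return EdgePValues(net=net, method="mlf", p=p)


def nc_pvalues(net: WeightedNetwork) -> EdgePValues:
    """Noise-corrected-filter p-values (binomial approximation, n = N_t)."""
    _require_integer(net, "nc")
    n_t = int(round(net.total_strength))
    if n_t < 1:
        raise FilterError("nc requires total strength >= 1")
    p: dict[tuple[str, str], float] = {}
    for u, v, w in net.edges():
        q = net.strength(u) * net.strength(v) / (float(n_t) * n_t)
        if q > 1.0:
            logger.warning(
                "nc: q_ij = %.3g > 1 for edge (%s, %s); clipping", q, u, v
            )
            q = 1.0
        p[edge_key(u, v)] = _binomial_survival(w, n_t, q)
    return EdgePValues(net=net, method="nc", p=p)
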