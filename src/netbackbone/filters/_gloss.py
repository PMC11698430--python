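"""Global statistical significance (GloSS) filter.

The null keeps the observed topology fixed and redraws every edge weight
from the empirical weight distribution P̂ of the whole network.

Two readings of that null are provided:

* ``marginal`` — an edge's weight is a single draw from P̂; the p-value is
  the global survival Pr(W >= w).  Simple, but then the p-value is a
  monotone function of the weight alone.
* ``conditional`` (default) — the null law of an edge's weight is
  conditioned on the observed strengths and degrees of its endpoints.
  Treating each endpoint's other k-1 incident weights as i.i.d. draws from
  P̂, the conditional law on the integer grid is

      p(w | s_i, s_j, k_i, k_j) ∝ P̂(w) · Q^(k_i-1)(s_i - w) · Q^(k_j-1)(s_j - w)

  where Q^(m) is the m-fold convolution of P̂ (Q^(0) = point mass at 0);
  the p-value is the normalized upper tail from w onward.  A degree-1
  endpoint pins the edge weight to its strength, so such edges get p = 1.
"""

from __future__ import annotations

import logging
from collections import Counter

import numpy as np

from ..graph import WeightedNetwork, edge_key
from ._base import EdgePValues, FilterError

logger = logging.getLogger(__name__)

__all__ = ["gloss_pvalues"]


def _marginal(net: WeightedNetwork) -> dict[tuple[str, str], float]:
    weights = np.array([w for _, _, w in net.edges()])
    m = len(weights)
    p = {}
    for u, v, w in net.edges():
        p[edge_key(u, v)] = float(np.count_nonzero(weights >= w) / m)
    return p


class _ConvolutionTable:
    """Cached m-fold convolutions of the empirical weight pmf on integers."""

    def __init__(self, pmf: np.ndarray):
        self.pmf = pmf  # index = weight, pmf[0] = 0
        self._powers: list[np.ndarray] = [np.array([1.0])]  # Q^(0) = δ_0

    def power(self, m: int) -> np.ndarray:
        while len(self._powers) <= m:
            self._powers.append(np.convolve(self._powers[-1], self.pmf))
        return self._powers[m]

    def at(self, m: int, t: int) -> float:
        q = self.power(m)
        if t < 0 or t >= len(q):
            return 0.0
        return float(q[t])


def _conditional(net: WeightedNetwork) -> dict[tuple[str, str], float]:
    weights = [int(round(w)) for _, _, w in net.edges()]
    wmax = max(weights)
    counts = Counter(weights)
    pmf = np.zeros(wmax + 1)
    for w, c in counts.items():
        pmf[w] = c / len(weights)
    table = _ConvolutionTable(pmf)
    support = np.arange(wmax + 1)

    p: dict[tuple[str, str], float] = {}
    for u, v, w in net.edges():
        w = int(round(w))
        ki, kj = net.degree(u), net.degree(v)
        si, sj = int(round(net.strength(u))), int(round(net.strength(v)))
        qi = table.power(ki - 1)
        qj = table.power(kj - 1)
        # score(w') = P̂(w') Q^(ki-1)(si - w') Q^(kj-1)(sj - w')
        score = np.zeros(wmax + 1)
        for wp in support[pmf > 0]:
            ti, tj = si - wp, sj - wp
            a = qi[ti] if 0 <= ti < len(qi) else 0.0
            b = qj[tj] if 0 <= tj < len(qj) else 0.0
            score[wp] = pmf[wp] * a * b
        total = score.sum()
        e = edge_key(u, v)
        if total <= 0.0:
            logger.warning(
                "gloss: empty conditional support for edge (%s, %s); p = 1",
                u,
                v,
            )
            p[e] = 1.0
        else:
            p[e] = float(min(1.0, score[w:].sum() / total))
    return p


def gloss_pvalues(net: WeightedNetwork, mode: str = "conditional") -> EdgePValues:
    """GloSS p-values under the fixed-topology weight-shuffling null.

    Parameters
    ----------
    net:
        The network to score.  The conditional mode requires integer
        weights (the convolutions live on the integer grid); the marginal
        mode accepts any positive weights.
    mode:
        ``"conditional"`` (default) or ``"marginal"``, see module docstring.
    """
    if mode not in ("conditional", "marginal"):
        raise ValueError(f"unknown gloss mode {mode!r}")
    if mode == "marginal":
        p = _marginal(net)
    else:
        if not net.has_integer_weights:
            raise FilterError(
                "gloss conditional mode requires integer weights; run "
                "graph.validate_for_method for scale-and-round guidance"
            )
        p = _conditional(net)
    return EdgePValues(net=net, method="gloss", p=p, params={"mode": mode})
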