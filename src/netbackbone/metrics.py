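"""Scalar measures used by the comparative evaluation.

Edge-level properties (weight, edge degree, edge betweenness), graph-level
properties (fractions, weight entropy, reachability, component count,
transitivity), rank correlation, the asymmetric overlap coefficient, and
the two-sample Kolmogorov–Smirnov statistic.

All functions accept a :class:`~netbackbone.graph.WeightedNetwork`, a
:class:`~netbackbone.corrections.Backbone`, or a bare ``networkx.Graph``
with ``weight`` edge attributes.  Undefined quantities (constant inputs,
empty graphs) are returned as ``nan`` with a logged warning rather than
raised, so sweeping studies can record them as missing.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .corrections import Backbone
from .graph import WeightedNetwork, edge_key

logger = logging.getLogger(__name__)

__all__ = [
    "spearman",
    "overlap_from",
    "edge_degree",
    "edge_betweenness",
    "weight_entropy",
    "reachability",
    "transitivity",
    "component_count",
    "ks_statistic",
    "GRAPH_PROPERTIES",
]

GraphLike = "WeightedNetwork | Backbone | nx.Graph"


def _as_graph(g) -> nx.Graph:
    if isinstance(g, WeightedNetwork):
        return g.graph
    if isinstance(g, Backbone):
        return g.subgraph()
    if isinstance(g, nx.Graph):
        return g
    raise TypeError(f"expected a network, backbone or graph, got {type(g)!r}")


# -- correlation and set similarity ---------------------------------------


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Tie-aware Spearman rank correlation (mean ranks on ties).

    Returns ``nan`` with a warning when either input is constant — the
    rank correlation is undefined there.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("inputs must have equal length")
    if len(x) < 2:
        raise ValueError("need at least two observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        logger.warning("spearman: constant input, correlation undefined")
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


def overlap_from(X: Iterable, Y: Iterable) -> float:
    """Asymmetric overlap |X ∩ Y| / |X| — the fraction of X inside Y."""
    X, Y = set(X), set(Y)
    if not X:
        logger.warning("overlap_from: empty reference set, overlap undefined")
        return float("nan")
    return len(X & Y) / len(X)


# -- edge-level properties -------------------------------------------------


def edge_degree(net) -> dict[tuple[str, str], float]:
    """Edge degree k(i,j) = k_i · k_j; large values flag hub–hub edges."""
    g = _as_graph(net)
    return {
        edge_key(u, v): g.degree(u) * g.degree(v) for u, v in g.edges
    }


def edge_betweenness(net, weighted: bool = False) -> dict[tuple[str, str], float]:
    """Edge betweenness: sum over unordered node pairs of the fraction of
    shortest paths through the edge.

    Shortest paths are hop counts by default; ``weighted=True`` uses
    distance 1/w so heavy edges are short.
    """
    g = _as_graph(net)
    if weighted:
        g = g.copy()
        dist = {(u, v): 1.0 / d["weight"] for u, v, d in g.edges(data=True)}
        nx.set_edge_attributes(g, dist, "_inv_weight")
        bc = nx.edge_betweenness_centrality(
            g, normalized=False, weight="_inv_weight"
        )
    else:
        bc = nx.edge_betweenness_centrality(g, normalized=False)
    return {edge_key(u, v): float(b) for (u, v), b in bc.items()}


# -- graph-level properties ------------------------------------------------


def weight_entropy(net, binned: int | None = None) -> float:
    """Shannon entropy (bits) of the edge-weight distribution.

    By default the distribution is the weight *shares* q_e = w_e / Σw —
    scale-invariant and defined for any positive weights.  ``binned=k``
    instead histograms the weights into k equal-width bins and uses the
    bin frequencies.
    """
    g = _as_graph(net)
    w = np.array([d["weight"] for _, _, d in g.edges(data=True)], dtype=float)
    if w.size == 0:
        logger.warning("weight_entropy: empty graph")
        return float("nan")
    if binned is not None:
        counts, _ = np.histogram(w, bins=binned)
        q = counts[counts > 0] / counts.sum()
    else:
        q = w / w.sum()
    return float(-(q * np.log2(q)).sum())


def reachability(net) -> float:
    """Fraction of ordered node pairs joined by a path, over the graph's
    own node set; 1 for a connected graph."""
    g = _as_graph(net)
    n = g.number_of_nodes()
    if n < 2:
        logger.warning("reachability: fewer than 2 nodes")
        return float("nan")
    pairs = sum(
        len(c) * (len(c) - 1) for c in nx.connected_components(g)
    )
    return pairs / (n * (n - 1))


def transitivity(net) -> float:
    """3 × triangles / connected triples; 0 when there are no triples."""
    return float(nx.transitivity(_as_graph(net)))


def component_count(net) -> int:
    """Number of connected components."""
    return nx.number_connected_components(_as_graph(net))


#: Graph-level properties of the global-property study, in report order.
GRAPH_PROPERTIES = (
    "edge_fraction",
    "node_fraction",
    "weight_fraction",
    "weight_entropy",
    "reachability",
    "components",
    "transitivity",
)


# -- distribution comparison ----------------------------------------------


def ks_statistic(sample_a: Sequence[float], sample_b: Sequence[float]) -> float:
    """Two-sample Kolmogorov–Smirnov statistic: the largest absolute gap
    between the two empirical CDFs."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        logger.warning("ks_statistic: empty sample")
        return float("nan")
    return float(stats.ks_2samp(a, b).statistic)
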