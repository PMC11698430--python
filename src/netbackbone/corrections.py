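"""Multiple-testing correction and backbone extraction.

Filtering a network tests one hypothesis per edge, so the raw per-edge
p-values face a multiplicity problem: at significance level α the expected
number of false positives grows with the edge count m.  Two standard
remedies are provided, both returning *adjusted* p-values so downstream
analyses can correlate them directly:

* Bonferroni: ``p_adj = min(1, p · m)`` — controls the family-wise error
  rate; equivalent to testing raw p against α/m.
* Benjamini–Hochberg step-up: ``p_adj(i) = min(1, min_{j>=i} m·p_(j)/j)``
  on the ascending-sorted p-values — controls the false discovery rate.

A backbone retains the edges whose (possibly adjusted) p-value is at most
α; boundary ties are kept.  Nodes that lose all their edges drop out of
the backbone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import networkx as nx
from statsmodels.stats.multitest import multipletests

from .filters import EdgePValues
from .graph import WeightedNetwork

__all__ = [
    "bonferroni_adjust",
    "bh_adjust",
    "adjust",
    "extract_backbone",
    "Backbone",
]

CORRECTIONS = ("none", "bonferroni", "fdr_bh")


def _adjust(pvals: EdgePValues, method: str) -> EdgePValues:
    edges = list(pvals.p)
    raw = [pvals.p[e] for e in edges]
    adj = multipletests(raw, method=method)[1]
    return dataclasses.replace(
        pvals,
        p=dict(zip(edges, (float(a) for a in adj))),
        side=None,
        correction={"bonferroni": "bonferroni", "fdr_bh": "fdr_bh"}[method],
    )


def bonferroni_adjust(pvals: EdgePValues) -> EdgePValues:
    """Bonferroni-adjusted p-values: ``min(1, p · m)`` per edge."""
    return _adjust(pvals, "bonferroni")


def bh_adjust(pvals: EdgePValues) -> EdgePValues:
    """Benjamini–Hochberg step-up adjusted p-values."""
    return _adjust(pvals, "fdr_bh")


def adjust(pvals: EdgePValues, correction: str) -> EdgePValues:
    """Apply a named correction (``none``, ``bonferroni``, ``fdr_bh``)."""
    if correction == "none":
        return pvals
    if correction == "bonferroni":
        return bonferroni_adjust(pvals)
    if correction == "fdr_bh":
        return bh_adjust(pvals)
    raise ValueError(
        f"unknown correction {correction!r}; expected one of {CORRECTIONS}"
    )


@dataclass
class Backbone:
    """Retained-edge subgraph with extraction provenance.

    The node set is exactly the set of endpoints of retained edges —
    nodes that lose every incident edge are not part of the backbone.
    """

    net: WeightedNetwork
    edges: frozenset[tuple[str, str]]
    method: str
    alpha: float
    correction: str

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(n for e in self.edges for n in e)

    def number_of_edges(self) -> int:
        return len(self.edges)

    def number_of_nodes(self) -> int:
        return len(self.nodes)

    @property
    def total_weight(self) -> float:
        return sum(self.net.weight(u, v) for u, v in self.edges)

    def is_proper(self) -> bool:
        """True iff the backbone is a strict, nonempty subset of the edges."""
        return 0 < len(self.edges) < self.net.number_of_edges()

    def subgraph(self) -> nx.Graph:
        """The backbone as a ``networkx`` graph (possibly empty)."""
        g = nx.Graph()
        for u, v in sorted(self.edges):
            g.add_edge(u, v, weight=self.net.weight(u, v))
        return g

    def to_network(self) -> WeightedNetwork:
        """The backbone as a :class:`WeightedNetwork`; errors if empty."""
        return WeightedNetwork(self.subgraph(), name=f"{self.net.name}-backbone")


def extract_backbone(
    net: WeightedNetwork,
    pvals: EdgePValues,
    alpha: float = 0.05,
    correction: str = "none",
) -> Backbone:
    """Retain the edges whose corrected p-value is at most ``alpha``."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if pvals.net is not net:
        raise ValueError("p-values were computed on a different network")
    corrected = adjust(pvals, correction)
    retained = frozenset(e for e, p in corrected.p.items() if p <= alpha)
    return Backbone(
        net=net,
        edges=retained,
        method=pvals.method,
        alpha=alpha,
        correction=correction,
    )
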