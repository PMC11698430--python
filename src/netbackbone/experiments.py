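"""The comparative-evaluation pipeline over many networks and methods.

Five studies, each consuming a list of networks and a list of filter
names and emitting tidy, plot-ready tables:

* :func:`similarity_study` — Spearman rank correlation between each pair
  of methods' edge p-value vectors, aggregated to mean/σ matrices.
* :func:`overlap_study` — asymmetric overlap coefficients between each
  ordered pair of methods' α-backbones, aggregated the same way.
* :func:`local_property_study` — Spearman correlation between each
  method's edge p-values and edge weight / edge degree / edge betweenness
  on the original network.
* :func:`global_property_study` — seven graph-level properties of each
  backbone, normalized by the original network's value, plus their pooled
  counter-cumulative distributions across networks.
* :func:`distribution_rank_study` — two-sample KS distance between
  backbone and original weight/degree distributions, with per-network
  method ranks (1 = closest to the original).

:func:`extraction_rate_table` accounts for which (method, correction)
cells produced a *proper* backbone (neither all edges kept nor all
removed, and no filter failure) — aggregated as a percentage of networks.

Aggregation uses the population standard deviation (divisor N).  A method
failing on a network (e.g. a non-convergent ensemble fit) excludes that
cell with a log message; it never aborts the other cells.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import metrics
from .corrections import Backbone, adjust, extract_backbone
from .filters import EdgePValues, FilterError, compute_pvalues
from .graph import WeightedNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "PValueCache",
    "similarity_study",
    "overlap_study",
    "local_property_study",
    "global_property_study",
    "distribution_rank_study",
    "extraction_rate_table",
    "ccdf_table",
]


@dataclass
class PValueCache:
    """Caches per-(network, method) p-values and remembers failures."""

    method_params: dict[str, dict] = field(default_factory=dict)
    _store: dict[tuple[int, str], EdgePValues] = field(default_factory=dict)
    failures: list[dict] = field(default_factory=list)

    def get(self, net: WeightedNetwork, method: str) -> EdgePValues | None:
        key = (id(net), method)
        if key in self._store:
            return self._store[key]
        try:
            pv = compute_pvalues(net, method, **self.method_params.get(method, {}))
        except FilterError as err:
            logger.warning("%s failed on %s: %s", method, net.name, err)
            self.failures.append(
                {"network": net.name, "method": method, "error": str(err)}
            )
            self._store[key] = None
            return None
        self._store[key] = pv
        return pv


def _named(nets) -> list[tuple[str, WeightedNetwork]]:
    return [(net.name, net) for net in nets]


def _aggregate(records: pd.DataFrame, index: list[str], value: str):
    """Mean and population-σ pivot tables over networks."""
    grouped = records.groupby(index)[value]
    mu = grouped.mean()
    sigma = grouped.apply(lambda v: float(np.std(v, ddof=0)))
    return mu, sigma


# -- similarity ------------------------------------------------------------


def similarity_study(
    nets,
    methods,
    correction: str = "none",
    cache: PValueCache | None = None,
):
    """Per-network Spearman correlation between method pairs' p-values.

    P-value vectors are aligned on each network's full (sorted) edge set,
    so no imputation is needed; ``correction`` optionally adjusts both
    vectors before correlating.  Returns ``(mu, sigma, records)`` where
    ``mu``/``sigma`` are method × method DataFrames aggregated over
    networks and ``records`` the long per-network table.
    """
    cache = cache or PValueCache()
    rows = []
    for name, net in _named(nets):
        vectors = {}
        for m in methods:
            pv = cache.get(net, m)
            if pv is not None:
                vectors[m] = adjust(pv, correction).vector()
        for m1, m2 in itertools.product(methods, methods):
            if m1 not in vectors or m2 not in vectors:
                continue
            r = metrics.spearman(vectors[m1], vectors[m2])
            if math.isnan(r):
                logger.warning(
                    "similarity: constant p-values for (%s, %s) on %s",
                    m1,
                    m2,
                    name,
                )
                continue
            rows.append(
                {"network": name, "method_a": m1, "method_b": m2, "spearman": r}
            )
    records = pd.DataFrame(rows)
    if records.empty:
        empty = pd.DataFrame(index=methods, columns=methods, dtype=float)
        return empty, empty.copy(), records
    mu, sigma = _aggregate(records, ["method_a", "method_b"], "spearman")
    shape = dict(index="method_a", columns="method_b", values="spearman")
    mu = mu.reset_index().pivot(**shape).reindex(index=methods, columns=methods)
    sigma = (
        sigma.reset_index().pivot(**shape).reindex(index=methods, columns=methods)
    )
    return mu, sigma, records


# -- overlap ---------------------------------------------------------------


def overlap_study(
    nets,
    methods,
    alpha: float = 0.05,
    correction: str = "fdr_bh",
    cache: PValueCache | None = None,
):
    """Asymmetric backbone overlap |X ∩ Y| / |X| for ordered method pairs.

    Empty backbones yield missing entries (logged), consistent with the
    extraction-rate accounting.  Returns ``(mu, sigma, records)``.
    """
    cache = cache or PValueCache()
    rows = []
    for name, net in _named(nets):
        backbones = {}
        for m in methods:
            pv = cache.get(net, m)
            if pv is None:
                continue
            backbones[m] = extract_backbone(net, pv, alpha, correction)
        for m1, m2 in itertools.product(methods, methods):
            if m1 not in backbones or m2 not in backbones:
                continue
            e1, e2 = backbones[m1].edges, backbones[m2].edges
            if not e1:
                logger.warning(
                    "overlap: empty %s backbone on %s; cell missing", m1, name
                )
                continue
            rows.append(
                {
                    "network": name,
                    "method_a": m1,
                    "method_b": m2,
                    "overlap": metrics.overlap_from(e1, e2),
                }
            )
    records = pd.DataFrame(rows)
    if records.empty:
        empty = pd.DataFrame(index=methods, columns=methods, dtype=float)
        return empty, empty.copy(), records
    mu, sigma = _aggregate(records, ["method_a", "method_b"], "overlap")
    shape = dict(index="method_a", columns="method_b", values="overlap")
    mu = mu.reset_index().pivot(**shape).reindex(index=methods, columns=methods)
    sigma = (
        sigma.reset_index().pivot(**shape).reindex(index=methods, columns=methods)
    )
    return mu, sigma, records


# -- local edge properties -------------------------------------------------

EDGE_PROPERTIES = ("weight", "edge_degree", "edge_betweenness")


def local_property_study(
    nets,
    methods,
    correction: str = "none",
    properties=EDGE_PROPERTIES,
    cache: PValueCache | None = None,
) -> pd.DataFrame:
    """Spearman correlation between edge p-values and edge properties.

    Properties are computed on the original network.  Returns a long
    DataFrame (network, method, property, spearman); undefined
    correlations (constant vectors) are recorded as missing.
    """
    cache = cache or PValueCache()
    rows = []
    for name, net in _named(nets):
        edges = net.edge_set()
        prop_vectors = {}
        for prop in properties:
            if prop == "weight":
                vals = {e: net.weight(*e) for e in edges}
            elif prop == "edge_degree":
                vals = metrics.edge_degree(net)
            elif prop == "edge_betweenness":
                vals = metrics.edge_betweenness(net)
            else:
                raise ValueError(f"unknown edge property {prop!r}")
            prop_vectors[prop] = [vals[e] for e in edges]
        for m in methods:
            pv = cache.get(net, m)
            if pv is None:
                continue
            pvec = adjust(pv, correction).vector()
            for prop in properties:
                r = metrics.spearman(pvec, prop_vectors[prop])
                rows.append(
                    {
                        "network": name,
                        "method": m,
                        "property": prop,
                        "spearman": r,
                    }
                )
    return pd.DataFrame(rows)


# -- global backbone properties --------------------------------------------


def _global_property_row(net: WeightedNetwork, backbone: Backbone) -> dict:
    e0, n0, w0 = (
        net.number_of_edges(),
        net.number_of_nodes(),
        net.total_weight,
    )
    vals: dict[str, float] = {
        "edge_fraction": backbone.number_of_edges() / e0,
        "node_fraction": backbone.number_of_nodes() / n0,
        "weight_fraction": backbone.total_weight / w0,
    }
    if backbone.number_of_edges() == 0:
        vals["weight_entropy"] = float("nan")
        vals["reachability"] = float("nan")
        vals["components"] = float("nan")
        vals["transitivity"] = float("nan")
        return vals
    sub = backbone.subgraph()
    orig = {
        "weight_entropy": metrics.weight_entropy(net),
        "reachability": metrics.reachability(net),
        "components": metrics.component_count(net),
        "transitivity": metrics.transitivity(net),
    }
    back = {
        "weight_entropy": metrics.weight_entropy(sub),
        "reachability": metrics.reachability(sub),
        "components": metrics.component_count(sub),
        "transitivity": metrics.transitivity(sub),
    }
    for prop in orig:
        if orig[prop] == 0 or math.isnan(orig[prop]) or math.isnan(back[prop]):
            vals[prop] = float("nan")  # ratio undefined
        else:
            vals[prop] = back[prop] / orig[prop]
    return vals


def global_property_study(
    nets,
    methods,
    alpha: float = 0.05,
    corrections=("none", "fdr_bh"),
    cache: PValueCache | None = None,
) -> pd.DataFrame:
    """Graph-level backbone properties normalized by the original network.

    For each (network, method, correction): edge/node/weight fractions,
    and backbone-to-original ratios of weight entropy, reachability,
    component count and transitivity.  Returns a long DataFrame with one
    row per (network, method, correction, property) carrying the
    normalized value; use :func:`ccdf_table` for the pooled
    counter-cumulative distributions.
    """
    cache = cache or PValueCache()
    rows = []
    for name, net in _named(nets):
        for m in methods:
            pv = cache.get(net, m)
            if pv is None:
                continue
            for corr in corrections:
                backbone = extract_backbone(net, pv, alpha, corr)
                for prop, v in _global_property_row(net, backbone).items():
                    rows.append(
                        {
                            "network": name,
                            "method": m,
                            "correction": corr,
                            "property": prop,
                            "normalized": v,
                        }
                    )
    return pd.DataFrame(rows)


def ccdf_table(global_records: pd.DataFrame) -> pd.DataFrame:
    """Pooled counter-cumulative distributions of normalized properties.

    For each (method, correction, property): the sorted distinct values x
    with the fraction of networks whose normalized value is >= x.
    """
    rows = []
    keys = ["method", "correction", "property"]
    for (m, corr, prop), group in global_records.groupby(keys):
        vals = np.sort(group["normalized"].dropna().to_numpy())
        if vals.size == 0:
            continue
        for x in np.unique(vals):
            rows.append(
                {
                    "method": m,
                    "correction": corr,
                    "property": prop,
                    "value": float(x),
                    "tail_fraction": float(np.mean(vals >= x)),
                }
            )
    return pd.DataFrame(rows)


# -- distribution ranks ----------------------------------------------------


def distribution_rank_study(
    nets,
    methods,
    alpha: float = 0.05,
    correction: str = "none",
    min_edges: int = 1000,
    cache: PValueCache | None = None,
) -> pd.DataFrame:
    """KS distance between backbone and original distributions, with ranks.

    Weight and degree multisets of each α-backbone are compared with the
    original network's by the two-sample KS statistic; per network and
    distribution, methods are ranked ascending by KS (average ranks on
    ties, 1 = closest).  Only networks with at least ``min_edges`` edges
    participate; empty backbones leave the method unranked (logged).
    """
    cache = cache or PValueCache()
    rows = []
    for name, net in _named(nets):
        if net.number_of_edges() < min_edges:
            logger.info(
                "distributions: %s has %d < %d edges; skipped",
                name,
                net.number_of_edges(),
                min_edges,
            )
            continue
        orig_w = [w for _, _, w in net.edges()]
        orig_d = [net.degree(n) for n in net.nodes]
        for m in methods:
            pv = cache.get(net, m)
            if pv is None:
                continue
            backbone = extract_backbone(net, pv, alpha, correction)
            if backbone.number_of_edges() == 0:
                logger.warning(
                    "distributions: empty %s backbone on %s; unranked", m, name
                )
                continue
            bw = [net.weight(u, v) for u, v in backbone.edges]
            sub = backbone.subgraph()
            bd = [sub.degree(n) for n in sub.nodes]
            for dist, a, b in (
                ("weight", bw, orig_w),
                ("degree", bd, orig_d),
            ):
                rows.append(
                    {
                        "network": name,
                        "method": m,
                        "distribution": dist,
                        "ks": metrics.ks_statistic(a, b),
                    }
                )
    records = pd.DataFrame(rows)
    if records.empty:
        records["rank"] = []
        return records
    records["rank"] = records.groupby(["network", "distribution"])["ks"].rank(
        method="average"
    )
    return records


# -- extraction accounting -------------------------------------------------


def extraction_rate_table(
    nets,
    methods,
    alpha: float = 0.05,
    corrections=("none", "fdr_bh"),
    cache: PValueCache | None = None,
) -> pd.DataFrame:
    """Percentage of networks on which each method extracts a *proper*
    backbone (ran successfully, kept some but not all edges)."""
    cache = cache or PValueCache()
    rows = []
    nets = list(nets)
    for corr in corrections:
        for m in methods:
            proper = 0
            for name, net in _named(nets):
                pv = cache.get(net, m)
                if pv is None:
                    continue
                if extract_backbone(net, pv, alpha, corr).is_proper():
                    proper += 1
            rows.append(
                {
                    "method": m,
                    "correction": corr,
                    "extraction_pct": 100.0 * proper / len(nets),
                }
            )
    return pd.DataFrame(rows)
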