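"""Synthetic weighted networks with the structure the filters assume.

Real corpora of weighted networks (connectomes, interaction networks, food
webs, transport and social networks) share a few salient statistical
features: heavy-tailed degree sequences, broad multi-scale positive
integer weights, and a single dominant connected component.  The
generators here emulate exactly those features so every pipeline stage can
run and be tested without external data:

* :func:`fixture` — small named deterministic graphs anchoring the
  closed-form filter examples.
* :func:`gen_heterogeneous` — configuration-model graph from a truncated
  power-law degree sequence with i.i.d. integer weights; the largest
  connected component is kept, so reachability and component count of the
  original network are 1.
* :func:`gen_planted` — the same, plus a seeded random fraction of edges
  whose weight is multiplied by a boost factor: ground-truth "anomalously
  strong" edges that real data never labels, enabling recovery-style
  evaluation of every filter.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import networkx as nx
import numpy as np

from .corrections import Backbone
from .graph import WeightedNetwork, edge_key

__all__ = [
    "fixture",
    "gen_heterogeneous",
    "gen_planted",
    "recovery_metrics",
    "PlantedNetwork",
    "RecoveryMetrics",
    "FIXTURES",
    "WEIGHT_MODELS",
]

FIXTURES = (
    "triangle_unit",
    "path3_unit",
    "star5_geometric",
    "two_cliques",
    "conditional_gloss_30",
)

WEIGHT_MODELS = ("lognormal_int", "zipf_int", "poisson_shifted")


# -- named fixtures --------------------------------------------------------


def fixture(name: str) -> WeightedNetwork:
    """Deterministic named test graphs.

    ``triangle_unit``: 3-cycle, unit weights.  ``path3_unit``: path a–b–c,
    unit weights.  ``star5_geometric``: hub with five leaves, weights
    1,2,4,8,16.  ``two_cliques``: two 4-cliques joined by one bridge edge.
    ``conditional_gloss_30``: 30-node seeded sparse graph with integer
    weights 1–20 (low degrees, so conditional-null Monte-Carlo checks are
    tractable).
    """
    if name == "triangle_unit":
        return WeightedNetwork.from_edges(
            [("a", "b", 1), ("b", "c", 1), ("a", "c", 1)], name=name
        )
    if name == "path3_unit":
        return WeightedNetwork.from_edges(
            [("a", "b", 1), ("b", "c", 1)], name=name
        )
    if name == "star5_geometric":
        return WeightedNetwork.from_edges(
            [("hub", f"leaf{i}", 2**i) for i in range(5)], name=name
        )
    if name == "two_cliques":
        edges = []
        left = [f"l{i}" for i in range(4)]
        right = [f"r{i}" for i in range(4)]
        for group in (left, right):
            for i in range(4):
                for j in range(i + 1, 4):
                    edges.append((group[i], group[j], 1))
        edges.append(("l0", "r0", 1))  # bridge
        return WeightedNetwork.from_edges(edges, name=name)
    if name == "conditional_gloss_30":
        rng = np.random.default_rng(30)
        # random tree (low degrees) plus a few chords
        nodes = [f"n{i:02d}" for i in range(30)]
        edges = []
        for i in range(1, 30):
            j = int(rng.integers(max(0, i - 4), i))  # shallow attachment
            edges.append((nodes[i], nodes[j]))
        for _ in range(8):
            i, j = rng.choice(30, size=2, replace=False)
            if (nodes[i], nodes[j]) not in edges and (
                nodes[j],
                nodes[i],
            ) not in edges and i != j:
                edges.append((nodes[i], nodes[j]))
        weights = rng.integers(1, 21, size=len(edges))
        return WeightedNetwork.from_edges(
            [(u, v, int(w)) for (u, v), w in zip(edges, weights)], name=name
        )
    raise ValueError(f"unknown fixture {name!r}; expected one of {FIXTURES}")


# -- heterogeneous generator -----------------------------------------------


def _pareto_xmin_for_mean(
    target_mean: float, gamma: float, cutoff: int
) -> float:
    """Solve for the Pareto scale so the rounded, truncated degree law has
    the requested mean (bisection on a numeric expectation)."""

    ks = np.arange(1, cutoff + 1, dtype=float)

    def mean_for(xmin: float) -> float:
        # F(k) for Pareto(xmin, gamma), values below xmin have mass 0
        def cdf(t: np.ndarray) -> np.ndarray:
            t = np.maximum(t, xmin)
            return 1.0 - (xmin / t) ** (gamma - 1.0)

        upper = np.minimum(ks + 0.5, cutoff)
        lower = ks - 0.5
        pk = cdf(upper) - cdf(lower)
        pk[-1] += (xmin / cutoff) ** (gamma - 1.0)  # truncation mass at cutoff
        pk = np.maximum(pk, 0.0)
        pk[0] += 1.0 - pk.sum()  # rounding mass below 1.5 collapses to k=1
        return float((ks * pk).sum())

    lo, hi = 0.5, float(cutoff)
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if mean_for(mid) < target_mean:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _sample_degrees(
    n: int, mean_degree: float, gamma: float, rng: np.random.Generator
) -> list[int]:
    cutoff = max(3, int(round(math.sqrt(n * mean_degree))))
    xmin = _pareto_xmin_for_mean(mean_degree, gamma, cutoff)
    u = rng.random(n)
    raw = xmin * (1.0 - u) ** (-1.0 / (gamma - 1.0))
    ks = np.clip(np.round(raw), 1, cutoff).astype(int)
    if ks.sum() % 2 == 1:
        ks[int(rng.integers(n))] += 1
    return ks.tolist()


def _sample_weights(
    m: int, model: str, rng: np.random.Generator
) -> np.ndarray:
    if model == "lognormal_int":
        w = np.round(rng.lognormal(mean=1.0, sigma=1.0, size=m))
        return np.maximum(w, 1).astype(int)
    if model == "zipf_int":
        return np.minimum(rng.zipf(2.5, size=m), 10**6).astype(int)
    if model == "poisson_shifted":
        return (1 + rng.poisson(3.0, size=m)).astype(int)
    raise ValueError(
        f"unknown weight model {model!r}; expected one of {WEIGHT_MODELS}"
    )


def gen_heterogeneous(
    n: int = 500,
    mean_degree: float = 6.0,
    degree_exponent: float = 2.5,
    weight_model: str = "lognormal_int",
    seed: int = 0,
) -> WeightedNetwork:
    """Heavy-tailed weighted network from the configuration model.

    Draws a truncated power-law degree sequence (exponent
    ``degree_exponent``, cutoff ``sqrt(n · mean_degree)``, scale solved so
    the sequence hits ``mean_degree`` in expectation), wires it with the
    configuration model collapsed to a simple graph, keeps the largest
    connected component, and assigns i.i.d. integer weights >= 1 from the
    chosen model.  Fully determined by ``seed``.
    """
    if n < 10:
        raise ValueError("n must be at least 10")
    rng = np.random.default_rng(seed)
    last_err: Exception | None = None
    for _ in range(100):
        degrees = _sample_degrees(n, mean_degree, degree_exponent, rng)
        try:
            multi = nx.configuration_model(
                degrees, seed=int(rng.integers(2**31))
            )
        except nx.NetworkXError as err:  # infeasible sequence
            last_err = err
            continue
        simple = nx.Graph(multi)  # collapse parallel edges
        simple.remove_edges_from(nx.selfloop_edges(simple))
        if simple.number_of_edges() == 0:
            continue
        lcc = max(nx.connected_components(simple), key=len)
        g = simple.subgraph(lcc)
        edges = sorted(
            edge_key(f"v{u:04d}", f"v{v:04d}") for u, v in g.edges
        )
        weights = _sample_weights(len(edges), weight_model, rng)
        return WeightedNetwork.from_edges(
            [(u, v, int(w)) for (u, v), w in zip(edges, weights)],
            name=f"het-n{n}-s{seed}",
        )
    raise RuntimeError(
        f"could not realize a degree sequence after 100 attempts: {last_err}"
    )


# -- planted anomalies -----------------------------------------------------


@dataclass
class PlantedNetwork:
    """A generated network with ground-truth anomalously strong edges.

    ``planted`` maps every edge to True iff its baseline weight was
    multiplied by the boost factor; ``baseline`` records the pre-boost
    weights.
    """

    net: WeightedNetwork
    planted: dict[tuple[str, str], bool]
    baseline: dict[tuple[str, str], float]
    params: dict

    @property
    def planted_edges(self) -> frozenset[tuple[str, str]]:
        return frozenset(e for e, flag in self.planted.items() if flag)


def gen_planted(
    n: int = 500,
    mean_degree: float = 6.0,
    weight_model: str = "lognormal_int",
    rho: float = 0.05,
    boost: float = 10.0,
    degree_exponent: float = 2.5,
    seed: int = 0,
) -> PlantedNetwork:
    """Heterogeneous network with a planted fraction ``rho`` of edges whose
    weight is multiplied by ``boost`` (kept integer)."""
    if not 0.0 <= rho < 0.5:
        raise ValueError("rho must be in [0, 0.5)")
    if boost < 2:
        raise ValueError("boost must be >= 2")
    base = gen_heterogeneous(
        n=n,
        mean_degree=mean_degree,
        degree_exponent=degree_exponent,
        weight_model=weight_model,
        seed=seed,
    )
    rng = np.random.default_rng((seed, 0xB005))
    edges = base.edge_set()
    n_plant = int(round(rho * len(edges)))
    chosen = set(
        tuple(edges[i]) for i in rng.choice(len(edges), n_plant, replace=False)
    ) if n_plant else set()
    baseline = {e: base.weight(*e) for e in edges}
    boosted = [
        (u, v, baseline[(u, v)] * (int(boost) if (u, v) in chosen else 1))
        for u, v in edges
    ]
    net = WeightedNetwork.from_edges(
        boosted, name=f"planted-n{n}-s{seed}"
    )
    return PlantedNetwork(
        net=net,
        planted={e: e in chosen for e in edges},
        baseline=baseline,
        params={
            "n": n,
            "mean_degree": mean_degree,
            "weight_model": weight_model,
            "rho": rho,
            "boost": boost,
            "seed": seed,
        },
    )


class RecoveryMetrics(NamedTuple):
    precision: float
    recall: float


def recovery_metrics(planted: PlantedNetwork, backbone: Backbone) -> RecoveryMetrics:
    """Precision and recall of a backbone against the planted edge labels.

    ``nan`` where the denominator is empty (no retained edges / nothing
    planted).
    """
    if backbone.net is not planted.net:
        raise ValueError("backbone was extracted from a different network")
    retained = set(backbone.edges)
    truth = set(planted.planted_edges)
    precision = len(retained & truth) / len(retained) if retained else float("nan")
    recall = len(retained & truth) / len(truth) if truth else float("nan")
    return RecoveryMetrics(precision, recall)
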