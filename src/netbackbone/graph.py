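"""Weighted-network container, validation, and serialization.

The central object is :class:`WeightedNetwork`, an undirected simple graph
with strictly positive edge weights.  It caches the quantities every edge
filter needs: node degree ``k_i``, node strength ``s_i`` (sum of incident
weights), the total weight ``T`` and the total strength ``N_t = 2T``.

Networks are read from and written to tab-separated weighted edge lists
(``source<TAB>target<TAB>weight``, ``#`` comments) or GraphML with a
``weight`` edge attribute.  Node identifiers are opaque strings; every
iteration that can affect an output file is lexicographically ordered so
runs are bit-reproducible.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "WeightedNetwork",
    "NetworkValidationError",
    "EdgeListParseError",
    "ValidationReport",
    "read_network",
    "write_network",
    "validate_for_method",
    "edge_key",
    "METHODS",
    "INTEGER_WEIGHT_METHODS",
]

#: Canonical short names of the seven filters.
METHODS = ("df", "pf", "mlf", "nc", "ecm", "gloss", "lans")

#: Filters whose null models count discrete weight units.
INTEGER_WEIGHT_METHODS = frozenset({"pf", "mlf", "nc", "ecm", "gloss"})


class NetworkValidationError(ValueError):
    """Raised when a graph violates the weighted simple-graph contract."""


class EdgeListParseError(ValueError):
    """Raised on a malformed edge-list row; carries the 1-based line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


def edge_key(u: str, v: str) -> tuple[str, str]:
    """Canonical unordered representation of an edge between ``u`` and ``v``."""
    return (u, v) if u <= v else (v, u)


class WeightedNetwork:
    """Undirected simple graph with positive edge weights.

    Parameters
    ----------
    graph:
        A ``networkx.Graph`` whose every edge has a positive ``weight``
        attribute.  The graph is copied with node labels coerced to ``str``
        and validated; self-loops or non-positive weights raise
        :class:`NetworkValidationError`.
    name:
        Optional label used in result tables and log messages.
    """

    def __init__(self, graph: nx.Graph, name: str | None = None):
        if graph.is_directed() or graph.is_multigraph():
            raise NetworkValidationError(
                "only undirected simple graphs are supported"
            )
        g = nx.Graph()
        for u, v, data in graph.edges(data=True):
            su, sv = str(u), str(v)
            if su == sv:
                raise NetworkValidationError(f"self-loop at node {su!r}")
            if "weight" not in data:
                raise NetworkValidationError(f"edge ({su}, {sv}) has no weight")
            w = float(data["weight"])
            if not math.isfinite(w) or w <= 0:
                raise NetworkValidationError(
                    f"edge ({su}, {sv}) has non-positive weight {w}"
                )
            g.add_edge(su, sv, weight=w)
        if g.number_of_edges() == 0:
            raise NetworkValidationError("network has no edges")
        # isolated nodes are not represented: every stored node has k >= 1
        self._g = g
        self.name = name or "net"
        self._strength = {
            n: sum(d["weight"] for _, _, d in g.edges(n, data=True))
            for n in g.nodes
        }
        self._total_weight = sum(d["weight"] for _, _, d in g.edges(data=True))
        self._integer = all(
            float(d["weight"]).is_integer() for _, _, d in g.edges(data=True)
        )

    # -- construction ------------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str, float]],
        name: str | None = None,
    ) -> "WeightedNetwork":
        """Build a network from ``(u, v, w)`` triples.

        Duplicate rows for the same unordered pair have their weights summed
        (a warning is logged); self-loop rows are dropped with a warning.
        """
        g = nx.Graph()
        for u, v, w in edges:
            su, sv = str(u), str(v)
            w = float(w)
            if su == sv:
                logger.warning("dropping self-loop at node %r", su)
                continue
            if not math.isfinite(w) or w <= 0:
                raise NetworkValidationError(
                    f"edge ({su}, {sv}) has non-positive weight {w}"
                )
            if g.has_edge(su, sv):
                logger.warning(
                    "duplicate edge (%s, %s): summing weights", su, sv
                )
                g[su][sv]["weight"] += w
            else:
                g.add_edge(su, sv, weight=w)
        return cls(g, name=name)

    # -- basic accessors ---------------------------------------------------

    @property
    def graph(self) -> nx.Graph:
        """The underlying ``networkx`` graph (treat as read-only)."""
        return self._g

    @property
    def nodes(self) -> list[str]:
        """Node identifiers in lexicographic order."""
        return sorted(self._g.nodes)

    def number_of_nodes(self) -> int:
        return self._g.number_of_nodes()

    def number_of_edges(self) -> int:
        return self._g.number_of_edges()

    def edges(self) -> Iterator[tuple[str, str, float]]:
        """Yield ``(u, v, w)`` with u < v, in lexicographic edge order."""
        for u, v in self.edge_set():
            yield u, v, self._g[u][v]["weight"]

    def edge_set(self) -> list[tuple[str, str]]:
        """Canonical (sorted) list of unordered edge keys."""
        return sorted(edge_key(u, v) for u, v in self._g.edges)

    def has_edge(self, u: str, v: str) -> bool:
        return self._g.has_edge(u, v)

    def weight(self, u: str, v: str) -> float:
        return self._g[u][v]["weight"]

    def degree(self, n: str) -> int:
        return self._g.degree(n)

    def strength(self, n: str) -> float:
        """Sum of weights of the node's incident edges (``s_i``)."""
        return self._strength[n]

    @property
    def total_weight(self) -> float:
        """``T``: sum of edge weights, each edge counted once."""
        return self._total_weight

    @property
    def total_strength(self) -> float:
        """``N_t = sum_i s_i = 2T``."""
        return 2.0 * self._total_weight

    @property
    def has_integer_weights(self) -> bool:
        return self._integer

    def incident_weights(self, n: str) -> list[float]:
        return [d["weight"] for _, _, d in self._g.edges(n, data=True)]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"WeightedNetwork({self.name!r}, n={self.number_of_nodes()}, "
            f"m={self.number_of_edges()}, T={self._total_weight:g})"
        )


# -- I/O -------------------------------------------------------------------


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        return format
    if path.suffix.lower() == ".graphml":
        return "graphml"
    return "edgelist"


def read_network(
    path: str | Path,
    format: str | None = None,
    name: str | None = None,
) -> WeightedNetwork:
    """Read a weighted network from an edge-list TSV or GraphML file.

    Edge-list rows are ``source<TAB>target<TAB>weight`` (any run of
    whitespace is accepted as the separator); lines starting with ``#`` and
    blank lines are ignored.  Duplicate rows are merged by summing weights,
    self-loops dropped, each with a logged warning; non-positive weights are
    an error.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    label = name or path.stem
    if fmt == "graphml":
        g = nx.read_graphml(path)
        if g.is_directed():
            raise NetworkValidationError(
                f"{path}: directed GraphML is not supported"
            )
        return WeightedNetwork(g, name=label)
    if fmt != "edgelist":
        raise ValueError(f"unknown format {fmt!r}")

    triples: list[tuple[str, str, float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise EdgeListParseError(
                    f"expected 3 fields, got {len(parts)}: {line!r}", lineno
                )
            u, v, ws = parts
            try:
                w = float(ws)
            except ValueError:
                raise EdgeListParseError(
                    f"weight {ws!r} is not a number", lineno
                ) from None
            if not math.isfinite(w) or w <= 0:
                raise EdgeListParseError(
                    f"weight must be a positive finite number, got {ws}", lineno
                )
            triples.append((u, v, w))
    return WeightedNetwork.from_edges(triples, name=label)


def _format_weight(w: float) -> str:
    if float(w).is_integer():
        return str(int(w))
    return repr(float(w))  # shortest round-tripping decimal


def write_network(
    net: WeightedNetwork, path: str | Path, format: str | None = None
) -> None:
    """Write a network; round-trips node set, edge set and weights exactly."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "graphml":
        nx.write_graphml(net.graph, path)
        return
    if fmt != "edgelist":
        raise ValueError(f"unknown format {fmt!r}")
    with open(path, "w") as fh:
        fh.write("# source\ttarget\tweight\n")
        for u, v, w in net.edges():
            fh.write(f"{u}\t{v}\t{_format_weight(w)}\n")


# -- per-method validation -------------------------------------------------


class ValidationReport:
    """Outcome of :func:`validate_for_method`; truthy iff the network passes."""

    def __init__(self, method: str, ok: bool, messages: list[str]):
        self.method = method
        self.ok = ok
        self.messages = messages

    def __bool__(self) -> bool:
        return self.ok

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        status = "pass" if self.ok else "fail"
        return f"ValidationReport({self.method}: {status}, {self.messages})"


def validate_for_method(net: WeightedNetwork, method: str) -> ValidationReport:
    """Check whether a network satisfies a filter's weight requirements.

    The Pólya-urn, marginal-likelihood, noise-corrected, enhanced-
    configuration-model and GloSS nulls count discrete weight units and
    require integer weights; the disparity and LANS filters accept any
    positive weights.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    messages: list[str] = []
    ok = True
    if method in INTEGER_WEIGHT_METHODS and not net.has_integer_weights:
        ok = False
        messages.append(
            f"method {method!r} requires integer weights; scale the weights "
            "by a common factor and round (e.g. multiply by 10**d for d "
            "significant decimals) before filtering"
        )
    return ValidationReport(method, ok, messages)
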