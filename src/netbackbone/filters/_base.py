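"""Shared types for the edge-significance filters."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from ..graph import WeightedNetwork

__all__ = ["EdgePValues", "FilterError"]


class FilterError(RuntimeError):
    """A filter could not be applied to a network (bad weights, no fit...)."""


@dataclass
class EdgePValues:
    """Per-edge p-values for one filter applied to one network.

    Attributes
    ----------
    net:
        The network the p-values were computed on.
    method:
        Canonical filter name (``df``, ``pf``, ``mlf``, ``nc``, ``ecm``,
        ``gloss``, ``lans``).
    p:
        Mapping from canonical edge key ``(u, v)`` with ``u < v`` to the
        edge p-value in [0, 1].
    side:
        For the per-endpoint filters (df, pf, lans): mapping from edge key
        to the two one-sided p-values ``(p_u, p_v)`` in the key's node
        order; the edge p-value is their minimum.  ``None`` for the
        symmetric filters.
    params:
        The method parameters used (e.g. Pólya reinforcement ``a``).
    correction:
        ``"none"`` for raw p-values; set by the correction routines.
    """

    net: WeightedNetwork
    method: str
    p: dict[tuple[str, str], float]
    side: dict[tuple[str, str], tuple[float, float]] | None = None
    params: Mapping[str, object] = field(default_factory=dict)
    correction: str = "none"

    @property
    def m(self) -> int:
        """Number of tested edges (= number of hypotheses)."""
        return len(self.p)

    def vector(self) -> list[float]:
        """P-values in canonical (sorted) edge order."""
        return [self.p[e] for e in self.net.edge_set()]

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: source, target, weight, p_raw[, p_side_u, p_side_v]."""
        rows = []
        for u, v in self.net.edge_set():
            row = {
                "source": u,
                "target": v,
                "weight": self.net.weight(u, v),
                "p_raw": self.p[(u, v)],
            }
            if self.side is not None:
                row["p_side_u"], row["p_side_v"] = self.side[(u, v)]
            rows.append(row)
        return pd.DataFrame(rows)
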