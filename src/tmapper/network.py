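"""Directed transition networks over blocks of time points.

A transition network is a digraph whose nodes carry the member time points
and a probability measure proportional to dwell time.  Both the
ground-truth construction (from symbolic dynamics) and the data-driven
Temporal Mapper produce this container.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Hashable

import networkx as nx
import numpy as np

__all__ = ["TransitionNetwork"]


@dataclass
class TransitionNetwork:
    """A directed graph over blocks of time points with a dwell-time measure.

    Attributes
    ----------
    graph : nx.DiGraph
        Node identifiers are arbitrary hashables (block indices or attractor
        symbols).  Node attributes may include ``measure``, ``mean_rank``,
        ``dominant_label`` and per-channel means.
    members : dict
        node -> sorted integer array of member time indices.  Members
        partition [0..n_samples).
    n_samples : int
        Total number of time points.
    params : dict
        Construction parameters (k, delta, seed, ...), echoed in manifests.
    """

    graph: nx.DiGraph
    members: dict[Hashable, np.ndarray]
    n_samples: int
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.members = {
            n: np.asarray(ix, dtype=int) for n, ix in self.members.items()
        }
        counts = sum(len(ix) for ix in self.members.values())
        if counts != self.n_samples:
            raise ValueError(
                f"members must partition the {self.n_samples} time points "
                f"(covered {counts})"
            )
        for n in self.graph.nodes:
            self.graph.nodes[n]["measure"] = len(self.members[n]) / self.n_samples

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def node_order(self) -> list[Hashable]:
        """Deterministic node ordering (sorted by node id)."""
        return sorted(self.graph.nodes)

    def measure(self, order: list[Hashable] | None = None) -> np.ndarray:
        """Dwell-time probability vector, normalized to sum 1."""
        order = self.node_order() if order is None else order
        p = np.array([len(self.members[n]) for n in order], dtype=float)
        return p / p.sum()

    def block_of(self) -> np.ndarray:
        """Map each time index to its node id (object array for symbols)."""
        out = np.empty(self.n_samples, dtype=object)
        for n, ix in self.members.items():
            out[ix] = n
        return out

    def block_index_of(self) -> np.ndarray:
        """Map each time index to its node's position in node_order()."""
        order = {n: i for i, n in enumerate(self.node_order())}
        out = np.empty(self.n_samples, dtype=int)
        for n, ix in self.members.items():
            out[ix] = order[n]
        return out

    def is_strongly_connected(self) -> bool:
        return nx.is_strongly_connected(self.graph)
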