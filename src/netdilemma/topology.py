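"""Interaction structures for the networked Prisoner's Dilemma.

Two structures are supported:

* **ring** — a static circulant graph ``C_n(1, ..., k/2)``: player ``i`` is
  linked to the ``k/2`` nearest players on each side of a cycle.  This is the
  classic lattice on which network reciprocity can stabilize cooperation.
* **well_mixed_draw** — one independently sampled simple k-regular graph,
  redrawn every round, so each player keeps a per-round stake of ``k``
  neighbors while partner continuity is destroyed ("random one-shot"
  interactions).

Player indices are 0-based everywhere; edges are stored as unordered
``(min, max)`` pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import FrozenSet, Tuple

import networkx as nx
import numpy as np

__all__ = [
    "TopologyMode",
    "Topology",
    "InvalidDegreeError",
    "InfeasibleTopologyError",
    "make_ring",
    "resample_well_mixed",
]


class TopologyMode(str, Enum):
    RING = "ring"
    WELL_MIXED_DRAW = "well_mixed_draw"


class InvalidDegreeError(ValueError):
    """Raised when the requested degree is odd or non-positive."""


class InfeasibleTopologyError(ValueError):
    """Raised when no simple k-regular graph exists for (n, k)."""


Edge = Tuple[int, int]


@dataclass(frozen=True)
class Topology:
    """A k-regular interaction graph over player indices 0..n-1."""

    n_players: int
    degree: int
    adjacency: FrozenSet[Edge]
    mode: TopologyMode
    _neighbors: tuple = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        nbrs: list[list[int]] = [[] for _ in range(self.n_players)]
        for i, j in self.adjacency:
            if i == j:
                raise ValueError(f"self-loop at player {i}")
            nbrs[i].append(j)
            nbrs[j].append(i)
        for i, ns in enumerate(nbrs):
            if len(ns) != self.degree:
                raise ValueError(
                    f"player {i} has {len(ns)} neighbors, expected {self.degree}"
                )
        object.__setattr__(
            self, "_neighbors", tuple(tuple(sorted(ns)) for ns in nbrs)
        )

    def neighbors(self, player: int) -> Tuple[int, ...]:
        """Sorted neighbor indices of ``player``."""
        return self._neighbors[player]

    def to_edge_list(self) -> str:
        """Serialize as text: header ``# n=<n> k=<k> mode=<mode>``, one
        ``i j`` pair per line, edges sorted."""
        lines = [f"# n={self.n_players} k={self.degree} mode={self.mode.value}"]
        lines += [f"{i} {j}" for i, j in sorted(self.adjacency)]
        return "\n".join(lines) + "\n"


def _check_degree(n_players: int, degree: int) -> None:
    if degree < 2 or degree % 2 != 0:
        raise InvalidDegreeError(f"degree must be a positive even integer, got {degree}")
    if degree >= n_players:
        raise InfeasibleTopologyError(
            f"degree {degree} must be smaller than n_players {n_players}"
        )


def make_ring(n_players: int, degree: int) -> Topology:
    """Build the circulant ring ``C_n(1..k/2)``.

    Each player ``i`` is adjacent to ``(i ± d) mod n`` for
    ``d = 1 .. degree/2``.  Deterministic; no randomness involved.
    """
    _check_degree(n_players, degree)
    edges = set()
    for i in range(n_players):
        for d in range(1, degree // 2 + 1):
            j = (i + d) % n_players
            edges.add((min(i, j), max(i, j)))
    return Topology(n_players, degree, frozenset(edges), TopologyMode.RING)


def resample_well_mixed(
    n_players: int, degree: int, rng: np.random.Generator
) -> Topology:
    """Draw a fresh simple k-regular graph on ``n_players`` nodes.

    Used to realize the well-mixed condition: calling this every round
    destroys partner continuity while preserving each player's per-round
    degree (hence the cooperator's total cost 10k).

    The draw consumes entropy from ``rng``, so successive calls give
    independent graphs and a fixed seed is bit-reproducible.
    """
    _check_degree(n_players, degree)
    if (n_players * degree) % 2 != 0:
        raise InfeasibleTopologyError(
            f"no {degree}-regular graph on {n_players} nodes (n*k odd)"
        )
    seed = int(rng.integers(0, 2**31 - 1))
    g = nx.random_regular_graph(degree, n_players, seed=seed)
    edges = frozenset((min(i, j), max(i, j)) for i, j in g.edges())
    return Topology(n_players, degree, edges, TopologyMode.WELL_MIXED_DRAW)
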