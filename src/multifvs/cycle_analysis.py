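"""Simple-cycle enumeration and per-node loop-membership counting.

The greedy cross-layer solver ranks candidate driver nodes by how many
"passing loops" (directed simple cycles of the study layer) run through
them.  Enumeration is exhaustive but capped: past ``cap`` cycles the
result is flagged truncated and callers fall back to counting cycles up
to a length bound, since the ranking needs relative, not exact, counts.

A self-loop counts as a cycle of length 1.  Cycle identity is the node
sequence up to rotation (not reflection — the graphs are directed);
each cycle is stored in its canonical rotation starting at the smallest
node id, and the listing is sorted by (length, sequence) so it is
deterministic regardless of enumeration order.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import islice
from typing import Iterable, Mapping

import networkx as nx

from .multilayer_graph import Layer, NodeId

DEFAULT_CYCLE_CAP = 100_000
DEFAULT_LENGTH_BOUND = 12


@dataclass(frozen=True)
class CycleSet:
    """A (possibly truncated) listing of directed simple cycles."""

    cycles: tuple[tuple[NodeId, ...], ...]
    truncated: bool
    cap: int

    def __len__(self) -> int:
        return len(self.cycles)

    def __iter__(self):
        return iter(self.cycles)

    @property
    def node_sets(self) -> tuple[frozenset[NodeId], ...]:
        return tuple(frozenset(c) for c in self.cycles)

    def restrict_through(self, nodes: Iterable[NodeId]) -> "CycleSet":
        """Cycles passing through at least one of ``nodes``."""
        probe = set(nodes)
        kept = tuple(c for c in self.cycles if probe.intersection(c))
        return CycleSet(cycles=kept, truncated=self.truncated, cap=self.cap)


def _canonical(cycle: list[NodeId]) -> tuple[NodeId, ...]:
    """Rotate a cycle so it starts at its smallest node id."""
    i = cycle.index(min(cycle))
    return tuple(cycle[i:] + cycle[:i])


def enumerate_cycles(
    layer: Layer,
    cap: int = DEFAULT_CYCLE_CAP,
    length_bound: int | None = None,
) -> CycleSet:
    """Enumerate the directed simple cycles of a layer.

    Uses SCC-restricted backtracking (Johnson's algorithm) and stops
    after ``cap`` cycles, setting ``truncated``.  ``length_bound``
    restricts enumeration to cycles of at most that many nodes (the
    truncation fallback used by the greedy solver).
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    g = layer.to_networkx()
    it = nx.simple_cycles(g, length_bound=length_bound)
    raw = list(islice(it, cap + 1))
    truncated = len(raw) > cap
    if truncated:
        raw = raw[:cap]
    cycles = sorted({_canonical(c) for c in raw}, key=lambda c: (len(c), c))
    return CycleSet(cycles=tuple(cycles), truncated=truncated, cap=cap)


def loops_through(cycles: CycleSet, nodes: Iterable[NodeId]) -> dict[NodeId, int]:
    """Number of enumerated cycles containing each queried node."""
    counts = {n: 0 for n in nodes}
    for cyc in cycles:
        for n in cyc:
            if n in counts:
                counts[n] += 1
    return counts


def residual_cycles(
    layer: Layer,
    removed: Iterable[NodeId],
    cap: int = DEFAULT_CYCLE_CAP,
    length_bound: int | None = None,
) -> CycleSet:
    """Cycles of the induced subgraph after deleting ``removed``.

    Empty exactly when ``removed`` is an FVS of the layer.
    """
    return enumerate_cycles(
        layer.subgraph_without(removed), cap=cap, length_bound=length_bound
    )
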