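"""Single-layer minimum feedback vertex set (MFVS) machinery.

An FVS of a directed graph is a node set whose removal leaves the graph
without directed cycles; the MFVS is a minimum-cardinality one.  The
solver here — simplification to a reduced core followed by exact
branch-and-bound search, the combination referred to as the SG
algorithm — applies three classic FVS-preserving reductions to a
fixpoint:

R1  a node with a self-loop belongs to every FVS: force it, delete it;
R2  a node with in-degree 0 or out-degree 0 lies on no cycle: delete it;
R3  a node with in-degree 1 (resp. out-degree 1) and no self-loop can be
    contracted into its sole predecessor (resp. successor) — every cycle
    through it also passes the neighbour, so the neighbour dominates it.

The residual is decomposed into strongly connected components and each
component is solved exactly by branching over the vertices of a
shortest cycle (every FVS must contain at least one of them), pruned by
the incumbent and a vertex-disjoint-cycle-packing lower bound.

``brute_force_mfvs`` is an independent subset-enumeration oracle used
to validate the solver on small graphs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable

import networkx as nx

from .multilayer_graph import Layer, NodeId


class FvsBudgetError(RuntimeError):
    """A residual strongly connected component exceeds the exact-search
    node budget; fall back to a greedy method or raise the budget."""


@dataclass(frozen=True)
class FvsResult:
    """A feedback vertex set for one layer with validity metadata."""

    layer_id: str
    fvs: frozenset[NodeId]
    method: str  # "SG", "ISG", "IISG" or "oracle"
    is_valid: bool

    @property
    def size(self) -> int:
        return len(self.fvs)


@dataclass(frozen=True)
class ReductionTrace:
    """Outcome of exhaustive R1–R3 simplification.

    ``forced_nodes`` belong to every MFVS; ``removed_nodes`` lie on no
    cycle; ``contracted_pairs`` records each R3 merge as ``(node,
    absorbed_into)``; ``residual`` is the irreducible core, satisfying
    MFVS(layer) = forced_nodes ∪ MFVS(residual).
    """

    forced_nodes: frozenset[NodeId]
    removed_nodes: frozenset[NodeId]
    contracted_pairs: tuple[tuple[NodeId, NodeId], ...]
    residual: Layer


def is_fvs(layer: Layer, candidate: Iterable[NodeId]) -> bool:
    """True iff removing ``candidate`` leaves the layer acyclic."""
    cand = set(candidate)
    return nx.is_directed_acyclic_graph(layer.subgraph_without(cand).to_networkx())


def _reduce_graph(g: nx.DiGraph):
    """Apply R1–R3 to a fixpoint on a copy of ``g``.

    Returns ``(forced, removed, contracted, residual_graph)``.  Node
    scans run in sorted order so the outcome is deterministic.
    """
    h = g.copy()
    forced: set[NodeId] = set()
    removed: set[NodeId] = set()
    contracted: list[tuple[NodeId, NodeId]] = []
    changed = True
    while changed:
        changed = False
        for v in sorted(h.nodes):
            if h.has_edge(v, v):
                forced.add(v)
                h.remove_node(v)
            elif h.in_degree(v) == 0 or h.out_degree(v) == 0:
                removed.add(v)
                h.remove_node(v)
            elif h.in_degree(v) == 1:
                (u,) = h.predecessors(v)
                for w in list(h.successors(v)):
                    h.add_edge(u, w)
                h.remove_node(v)
                contracted.append((v, u))
            elif h.out_degree(v) == 1:
                (w,) = h.successors(v)
                for p in list(h.predecessors(v)):
                    h.add_edge(p, w)
                h.remove_node(v)
                contracted.append((v, w))
            else:
                continue
            changed = True
            break
    return forced, removed, contracted, h


def simplify(layer: Layer) -> ReductionTrace:
    """Exhaustively simplify a layer with reductions R1–R3.

    The trace satisfies |MFVS(layer)| = |forced_nodes| + |MFVS(residual)|,
    and forced_nodes united with any MFVS of the residual is an MFVS of
    the original layer (contractions keep the surviving endpoint's id,
    so no un-contraction mapping is needed for the node set itself).
    """
    forced, removed, contracted, h = _reduce_graph(layer.to_networkx())
    residual = Layer(
        layer_id=layer.layer_id,
        nodes=frozenset(h.nodes),
        edges=frozenset(h.edges),
    )
    return ReductionTrace(
        forced_nodes=frozenset(forced),
        removed_nodes=frozenset(removed),
        contracted_pairs=tuple(contracted),
        residual=residual,
    )


def _shortest_cycle(h: nx.DiGraph) -> list[NodeId]:
    """A shortest directed cycle of ``h`` (as a node list), chosen
    deterministically.  ``h`` must contain at least one cycle and no
    self-loops (R1 removes those first)."""
    best: list[NodeId] | None = None
    for v in sorted(h.nodes):
        if best is not None and len(best) == 2:
            break
        # shortest path from any successor of v back to v closes the
        # shortest cycle through v
        try:
            paths = nx.single_source_shortest_path(h, v, cutoff=None if best is None else len(best) - 1)
        except nx.NetworkXError:  # pragma: no cover
            continue
        for u in sorted(h.predecessors(v)):
            if u in paths and len(paths[u]) >= 2:
                cyc = paths[u]
                if best is None or len(cyc) < len(best):
                    best = cyc
    if best is None:
        raise AssertionError("no cycle found in a graph expected to be cyclic")
    return best


def _cycle_packing_lower_bound(h: nx.DiGraph) -> int:
    """Greedy count of vertex-disjoint cycles: a lower bound on |MFVS|."""
    g = h.copy()
    count = 0
    while True:
        g = _strip_acyclic(g)
        if g.number_of_nodes() == 0:
            return count
        cyc = _shortest_cycle(g)
        g.remove_nodes_from(cyc)
        count += 1


def _strip_acyclic(g: nx.DiGraph) -> nx.DiGraph:
    """Restrict to nodes lying on some cycle (non-trivial SCCs or self-loops)."""
    keep: set[NodeId] = set()
    for comp in nx.strongly_connected_components(g):
        if len(comp) > 1:
            keep |= comp
        else:
            (v,) = comp
            if g.has_edge(v, v):
                keep.add(v)
    return g.subgraph(keep).copy()


def _bb_mfvs(g: nx.DiGraph, budget: int) -> frozenset[NodeId] | None:
    """Minimum FVS of ``g`` if its size is <= ``budget``, else None.

    Branches over the vertices of a shortest cycle; among equal-size
    optima, prefers the lexicographically smaller sorted node tuple
    reachable through the reduction-pruned search.
    """
    forced, _, _, h = _reduce_graph(g)
    if len(forced) > budget:
        return None
    if h.number_of_nodes() == 0:
        return frozenset(forced)
    if len(forced) + _cycle_packing_lower_bound(h) > budget:
        return None
    cycle = _shortest_cycle(h)
    best: frozenset[NodeId] | None = None
    for v in sorted(cycle):
        rem = (budget if best is None else len(best) - len(forced)) - 1
        h2 = h.copy()
        h2.remove_node(v)
        sub = _bb_mfvs(h2, rem)
        if sub is None:
            continue
        cand = frozenset(forced) | {v} | sub
        if best is None or (len(cand), tuple(sorted(cand))) < (
            len(best),
            tuple(sorted(best)),
        ):
            best = cand
    return best


def exact_mfvs(layer: Layer, node_budget: int = 40) -> FvsResult:
    """Exact MFVS: simplify, split into SCCs, branch-and-bound per SCC.

    Raises :class:`FvsBudgetError` if a residual SCC has more than
    ``node_budget`` nodes after simplification (real regulatory
    networks reduce to far smaller cores; for larger ones use a greedy
    heuristic or raise the budget).
    """
    trace = simplify(layer)
    fvs: set[NodeId] = set(trace.forced_nodes)
    g = trace.residual.to_networkx()
    for comp in sorted(nx.strongly_connected_components(g), key=lambda c: sorted(c)):
        if len(comp) == 1:
            (v,) = comp
            if not g.has_edge(v, v):
                continue
        if len(comp) > node_budget:
            raise FvsBudgetError(
                f"residual SCC of {len(comp)} nodes exceeds the exact-search "
                f"budget ({node_budget}); use a greedy fallback or raise node_budget"
            )
        sub = _bb_mfvs(g.subgraph(comp).copy(), budget=len(comp))
        assert sub is not None
        fvs |= sub
    result = frozenset(fvs)
    return FvsResult(
        layer_id=layer.layer_id,
        fvs=result,
        method="SG",
        is_valid=is_fvs(layer, result),
    )


def sg_mfvs(layer: Layer, node_budget: int = 40) -> FvsResult:
    """The SG algorithm: simplification plus exact search (alias of
    :func:`exact_mfvs` with the ``"SG"`` method tag)."""
    return exact_mfvs(layer, node_budget=node_budget)


def brute_force_mfvs(layer: Layer, max_n: int = 15) -> FvsResult:
    """Subset-enumeration MFVS oracle (first valid set in increasing
    size, lexicographic within a size).  Exponential; refuses graphs
    with more than ``max_n`` nodes."""
    if layer.n_nodes > max_n:
        raise ValueError(
            f"brute force refused: {layer.n_nodes} nodes > max_n={max_n}"
        )
    nodes = sorted(layer.nodes)
    for size in range(len(nodes) + 1):
        for cand in combinations(nodes, size):
            if is_fvs(layer, cand):
                return FvsResult(
                    layer_id=layer.layer_id,
                    fvs=frozenset(cand),
                    method="oracle",
                    is_valid=True,
                )
    raise AssertionError("unreachable: the full node set is always an FVS")
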