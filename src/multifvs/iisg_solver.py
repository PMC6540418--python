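"""Minimum FVS-union solvers for multilayer networks: ISG, IISG, oracle.

Under the assumption that a node is either a driver in every layer or
in none, the minimal driver set of an S-layer network solves

    min |F_1 ∪ F_2 ∪ ... ∪ F_S|,   F_a an FVS of layer a.

Two heuristics are provided, plus an exact oracle for small instances:

* **ISG** — solve each layer independently with the exact single-layer
  SG solver and take the union.  Valid but typically oversized, since
  per-layer optima ignore each other.
* **IISG** — greedy improvement: compute the reference layer's MFVS
  F_r first, then cover each study layer's cycles preferring *dominated
  nodes* — nodes already in F_r, nodes on many passing loops, nodes
  with larger function weight — so the study-layer FVS reuses reference
  nodes and the union stays small.  One dominated node is committed per
  iteration and loop counts are recomputed after each removal.
* **min_union_oracle** — exhaustive subset enumeration of the true
  minimum union, for testing.

The dominated-node total order is lexicographic on (reference-FVS
membership desc, passing-loop count desc, function weight desc, node id
asc); the final tie on node id makes every run deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .cycle_analysis import (
    DEFAULT_CYCLE_CAP,
    DEFAULT_LENGTH_BOUND,
    CycleSet,
    enumerate_cycles,
    loops_through,
    residual_cycles,
)
from .fvs_core import FvsResult, is_fvs, sg_mfvs, exact_mfvs
from .multilayer_graph import FunctionWeights, Layer, MultilayerNetwork, NodeId

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DominatedScore:
    """Ranking tuple for one candidate dominated node."""

    node_id: NodeId
    in_reference_fvs: bool
    loop_count: int
    function_weight: float

    @property
    def sort_key(self):
        # descending on membership, loops, weight; ascending on id
        return (
            not self.in_reference_fvs,
            -self.loop_count,
            -self.function_weight,
            self.node_id,
        )


@dataclass(frozen=True)
class UnionResult:
    """A cross-layer driver-node set with per-layer validity."""

    driver_nodes: frozenset[NodeId]
    method: str  # "ISG", "IISG" or "oracle"
    layer_ids: tuple[str, ...]
    per_layer_valid: tuple[bool, ...]

    @property
    def size(self) -> int:
        return len(self.driver_nodes)

    @property
    def all_valid(self) -> bool:
        return all(self.per_layer_valid)


@dataclass(frozen=True)
class IisgState:
    """Working sets of one IISG run, kept for inspection.

    ``selection_trace`` logs every dominated-node commitment as
    ``(phase, DominatedScore)`` in order.
    """

    F_r: frozenset[NodeId]
    F_i: dict[str, frozenset[NodeId]] = field(default_factory=dict)
    selection_trace: tuple[tuple[str, DominatedScore], ...] = ()

    @property
    def F_union(self) -> frozenset[NodeId]:
        out = set(self.F_r)
        for fi in self.F_i.values():
            out |= fi
        return frozenset(out)


def _validities(net: MultilayerNetwork, drivers: frozenset[NodeId]):
    return tuple(is_fvs(lay, drivers) for lay in net.layers)


#: Default priority of the dominated-node criteria.
DEFAULT_CRITERIA = ("reference", "loops", "weight")

_CRITERION_KEYS = {
    "reference": lambda s: not s.in_reference_fvs,
    "loops": lambda s: -s.loop_count,
    "weight": lambda s: -s.function_weight,
}


def dominated_rank(
    candidates: Iterable[NodeId],
    L: CycleSet,
    F_r: Iterable[NodeId],
    w: FunctionWeights | None = None,
    criteria: Sequence[str] = DEFAULT_CRITERIA,
) -> list[DominatedScore]:
    """Rank candidate nodes by the dominated-node criteria.

    Only candidates lying on at least one cycle of ``L`` are eligible;
    an empty return signals the caller to advance to the next phase.
    ``criteria`` sets the lexicographic priority (default: reference-FVS
    membership, then passing-loop count, then function weight); node id
    always breaks remaining ties, so the ranking is a total order.
    """
    if w is None:
        w = FunctionWeights.zero()
    unknown = set(criteria) - set(_CRITERION_KEYS)
    if unknown:
        raise ValueError(f"unknown ranking criteria: {sorted(unknown)}")
    ref = set(F_r)
    counts = loops_through(L, candidates)
    scores = [
        DominatedScore(
            node_id=n,
            in_reference_fvs=n in ref,
            loop_count=counts[n],
            function_weight=w[n],
        )
        for n in counts
        if counts[n] > 0
    ]
    key = lambda s: tuple(_CRITERION_KEYS[c](s) for c in criteria) + (s.node_id,)
    return sorted(scores, key=key)


def _cycles_with_fallback(
    study: Layer,
    removed: set[NodeId],
    cap: int,
    length_bound: int,
) -> CycleSet:
    cs = residual_cycles(study, removed, cap=cap)
    if cs.truncated:
        logger.warning(
            "cycle enumeration truncated at %d; falling back to length bound %d",
            cap,
            length_bound,
        )
        cs = residual_cycles(study, removed, cap=cap, length_bound=length_bound)
    return cs


def _iisg_phase(
    study: Layer,
    F_r: frozenset[NodeId],
    w: FunctionWeights | None,
    cap: int,
    length_bound: int,
    exact_residual: bool,
    trace: list[tuple[str, DominatedScore]],
) -> frozenset[NodeId]:
    """Greedy study-layer FVS construction against a reference FVS.

    First loop: while any cycle of the (progressively reduced) study
    layer passes through an unused reference node, commit the top-ranked
    dominated node.  Second loop: cover the remaining cycles the same
    way (or, in ``exact_residual`` mode, with the exact solver on the
    residual graph).

    With an empty reference FVS there is nothing to reuse, so the
    greedy degenerates to the exact single-layer solver (an acyclic
    reference layer thus contributes nothing to the union).
    """
    if not F_r:
        return exact_mfvs(study).fvs
    F_i: set[NodeId] = set()
    while True:  # cycles through reference nodes
        cs = _cycles_with_fallback(study, F_i, cap, length_bound)
        active_ref = F_r - F_i
        L_i = cs.restrict_through(active_ref)
        if len(L_i) == 0:
            break
        candidates = {n for cyc in L_i for n in cyc}
        ranked = dominated_rank(candidates, L_i, F_r, w)
        pick = ranked[0]
        F_i.add(pick.node_id)
        trace.append(("reference-loops", pick))
        logger.info("IISG pick (reference loops): %s", pick)
    if exact_residual:
        residual_fvs = exact_mfvs(study.subgraph_without(F_i)).fvs
        F_i |= residual_fvs
        for n in sorted(residual_fvs):
            trace.append(
                ("exact-residual", DominatedScore(n, n in F_r, 0, 0.0))
            )
        return frozenset(F_i)
    while True:  # remaining cycles
        cs = _cycles_with_fallback(study, F_i, cap, length_bound)
        if len(cs) == 0:
            break
        candidates = {n for cyc in cs for n in cyc}
        ranked = dominated_rank(candidates, cs, F_r, w)
        pick = ranked[0]
        F_i.add(pick.node_id)
        trace.append(("residual-loops", pick))
        logger.info("IISG pick (residual loops): %s", pick)
    return frozenset(F_i)


def iisg_duplex(
    reference: Layer,
    study: Layer,
    w: FunctionWeights | None = None,
    cap: int = DEFAULT_CYCLE_CAP,
    length_bound: int = DEFAULT_LENGTH_BOUND,
    exact_residual: bool = False,
    node_budget: int = 40,
) -> UnionResult:
    """IISG on a duplex: reference MFVS, then greedy study-layer cover.

    Returns the union F_r ∪ F_i, a valid FVS of both layers.
    """
    if reference.nodes != study.nodes:
        raise ValueError("reference and study layers must share the node universe")
    F_r = sg_mfvs(reference, node_budget=node_budget).fvs
    trace: list[tuple[str, DominatedScore]] = []
    F_i = _iisg_phase(study, F_r, w, cap, length_bound, exact_residual, trace)
    drivers = frozenset(F_r | F_i)
    net = MultilayerNetwork((reference, study))
    return UnionResult(
        driver_nodes=drivers,
        method="IISG",
        layer_ids=(reference.layer_id, study.layer_id),
        per_layer_valid=_validities(net, drivers),
    )


def iisg(
    net: MultilayerNetwork,
    reference_index: int = 0,
    w: FunctionWeights | None = None,
    cap: int = DEFAULT_CYCLE_CAP,
    length_bound: int = DEFAULT_LENGTH_BOUND,
    exact_residual: bool = False,
    node_budget: int = 40,
) -> UnionResult:
    """IISG on an S-layer network by folding over the layers.

    The reference layer is solved exactly; each further layer is covered
    greedily with the accumulated driver set acting as the reference
    FVS, so later layers reuse earlier drivers wherever a cycle allows.
    """
    if not 0 <= reference_index < net.S:
        raise IndexError(f"reference_index {reference_index} out of range for S={net.S}")
    order = [reference_index] + [i for i in range(net.S) if i != reference_index]
    F_union: frozenset[NodeId] = sg_mfvs(
        net.layers[reference_index], node_budget=node_budget
    ).fvs
    trace: list[tuple[str, DominatedScore]] = []
    for idx in order[1:]:
        F_i = _iisg_phase(
            net.layers[idx], F_union, w, cap, length_bound, exact_residual, trace
        )
        F_union = frozenset(F_union | F_i)
    return UnionResult(
        driver_nodes=F_union,
        method="IISG",
        layer_ids=tuple(l.layer_id for l in net.layers),
        per_layer_valid=_validities(net, F_union),
    )


def isg(net: MultilayerNetwork, node_budget: int = 40) -> UnionResult:
    """Union of independently computed per-layer exact MFVSs."""
    drivers: set[NodeId] = set()
    for lay in net.layers:
        drivers |= sg_mfvs(lay, node_budget=node_budget).fvs
    drivers = frozenset(drivers)
    return UnionResult(
        driver_nodes=drivers,
        method="ISG",
        layer_ids=tuple(l.layer_id for l in net.layers),
        per_layer_valid=_validities(net, drivers),
    )


def min_union_oracle(net: MultilayerNetwork, max_n: int = 14) -> UnionResult:
    """Exact minimum-union driver set by subset enumeration.

    The smallest node set whose removal leaves every layer acyclic;
    refuses universes above ``max_n`` nodes.
    """
    if net.N > max_n:
        raise ValueError(f"oracle refused: N={net.N} > max_n={max_n}")
    graphs = [lay.to_networkx() for lay in net.layers]
    nodes = sorted(net.node_universe)
    for size in range(net.N + 1):
        for cand in combinations(nodes, size):
            cset = set(cand)
            if all(
                nx.is_directed_acyclic_graph(g.subgraph(g.nodes - cset))
                for g in graphs
            ):
                drivers = frozenset(cand)
                return UnionResult(
                    driver_nodes=drivers,
                    method="oracle",
                    layer_ids=tuple(l.layer_id for l in net.layers),
                    per_layer_valid=tuple(True for _ in net.layers),
                )
    raise AssertionError("unreachable: the full universe is always a union FVS")


def compare_methods(
    net: MultilayerNetwork,
    w: FunctionWeights | None = None,
    oracle_max_n: int = 14,
    node_budget: int = 40,
) -> pd.DataFrame:
    """Tabulate per-layer SG, ISG, IISG (and the oracle when feasible).

    One row per method with driver-set size, membership and per-layer
    validity — the machine analogue of a published method-comparison
    table.
    """
    rows = []

    def row(method: str, drivers: frozenset[NodeId], valid: Sequence[bool]):
        r = {
            "method": method,
            "size": len(drivers),
            "drivers": ",".join(sorted(drivers)),
        }
        for lay, ok in zip(net.layers, valid):
            r[f"valid_layer_{lay.layer_id}"] = bool(ok)
        rows.append(r)

    for lay in net.layers:
        res = sg_mfvs(lay, node_budget=node_budget)
        valid = [is_fvs(other, res.fvs) for other in net.layers]
        row(f"SG(layer {lay.layer_id})", res.fvs, valid)
    isg_res = isg(net, node_budget=node_budget)
    row("ISG", isg_res.driver_nodes, isg_res.per_layer_valid)
    iisg_res = iisg(net, w=w, node_budget=node_budget)
    row("IISG", iisg_res.driver_nodes, iisg_res.per_layer_valid)
    if net.N <= oracle_max_n:
        orc = min_union_oracle(net, max_n=oracle_max_n)
        row("oracle", orc.driver_nodes, orc.per_layer_valid)
    return pd.DataFrame(rows)
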