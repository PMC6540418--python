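"""Data model and I/O for directed layers and multiplex networks.

A :class:`Layer` is one directed interaction type on a shared node
universe; a :class:`MultilayerNetwork` stacks several layers over the
same node set.  Node ids are opaque strings (gene symbols such as
``GAG-POL`` are preserved verbatim; no case folding).  Parallel edges
collapse to one ordered pair; self-loops are kept — a self-loop is a
directed cycle and forces its node into every feedback vertex set.

Supported text formats:

* per-layer edge list: ``src<TAB>dst[<TAB>weight]``, ``#`` comments;
* multiplex extended edge list (the CoMuNe lab dialect):
  ``layer src dst weight`` with positive-integer layer ids;
* node-weight table: ``node<TAB>weight`` (non-negative "function
  weights" used to rank dominated nodes).

Edge weights are parsed but discarded: all algorithms here are purely
topological.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

logger = logging.getLogger(__name__)

NodeId = str
Edge = tuple[NodeId, NodeId]


class ParseError(ValueError):
    """Malformed input line; message carries the path and line number."""


@dataclass(frozen=True)
class Layer:
    """One directed interaction layer on a shared node universe.

    Parameters
    ----------
    layer_id
        Label identifying the interaction type (e.g. ``"1"`` or
        ``"signaling"``).
    nodes
        Node universe of the layer; may exceed the edge endpoints
        (isolated nodes are permitted).
    edges
        Unique ordered pairs ``(src, dst)``; self-loops allowed.
    """

    layer_id: str
    nodes: frozenset[NodeId]
    edges: frozenset[Edge]

    def __post_init__(self) -> None:
        for u, v in self.edges:
            if u not in self.nodes or v not in self.nodes:
                raise ValueError(f"edge ({u!r}, {v!r}) has endpoint outside node set")

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[NodeId, NodeId]],
        layer_id: str = "1",
        extra_nodes: Iterable[NodeId] = (),
    ) -> "Layer":
        edge_set = frozenset((str(u), str(v)) for u, v in edges)
        nodes = frozenset(n for e in edge_set for n in e) | frozenset(map(str, extra_nodes))
        return cls(layer_id=str(layer_id), nodes=nodes, edges=edge_set)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def self_loops(self) -> frozenset[NodeId]:
        return frozenset(u for u, v in self.edges if u == v)

    def to_networkx(self) -> nx.DiGraph:
        """Deterministically ordered DiGraph (nodes and edges sorted)."""
        g = nx.DiGraph()
        g.add_nodes_from(sorted(self.nodes))
        g.add_edges_from(sorted(self.edges))
        return g

    def subgraph_without(self, removed: Iterable[NodeId]) -> "Layer":
        """Induced sub-layer on ``nodes - removed``."""
        gone = set(removed)
        unknown = gone - set(self.nodes)
        if unknown:
            raise KeyError(f"unknown nodes: {sorted(unknown)}")
        keep = self.nodes - gone
        return Layer(
            layer_id=self.layer_id,
            nodes=frozenset(keep),
            edges=frozenset((u, v) for u, v in self.edges if u in keep and v in keep),
        )

    def with_universe(self, universe: Iterable[NodeId]) -> "Layer":
        """Expand (never shrink) the node set to ``universe``."""
        uni = frozenset(universe)
        if not self.nodes <= uni:
            raise ValueError("universe does not contain all layer nodes")
        return Layer(layer_id=self.layer_id, nodes=uni, edges=self.edges)


@dataclass(frozen=True)
class MultilayerNetwork:
    """Ordered directed layers over one shared node universe."""

    layers: tuple[Layer, ...]

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("a multilayer network needs at least one layer")
        uni = self.layers[0].nodes
        for lay in self.layers:
            if lay.nodes != uni:
                raise ValueError(
                    f"layer {lay.layer_id!r} node set differs from the shared universe"
                )

    @classmethod
    def from_layers(cls, layers: Iterable[Layer]) -> "MultilayerNetwork":
        """Build a network, expanding every layer to the union universe."""
        lays = list(layers)
        universe = frozenset(n for lay in lays for n in lay.nodes)
        return cls(tuple(lay.with_universe(universe) for lay in lays))

    @property
    def node_universe(self) -> frozenset[NodeId]:
        return self.layers[0].nodes

    @property
    def S(self) -> int:
        """Number of layers."""
        return len(self.layers)

    @property
    def N(self) -> int:
        """Number of nodes in the shared universe."""
        return len(self.node_universe)


@dataclass
class FunctionWeights:
    """Non-negative per-node "function weights" (Definition-3 style
    biological importance); unlisted nodes weigh 0."""

    weights: dict[NodeId, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        import math

        for node, w in self.weights.items():
            if not math.isfinite(w) or w < 0:
                raise ValueError(f"weight for {node!r} must be finite and >= 0, got {w}")

    def __getitem__(self, node: NodeId) -> float:
        return self.weights.get(node, 0.0)

    def __len__(self) -> int:
        return len(self.weights)

    @classmethod
    def zero(cls) -> "FunctionWeights":
        return cls({})


def _tokenize(path: Path) -> Iterable[tuple[int, list[str]]]:
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split()


def read_edge_list(path: str | Path, layer_id: str = "1") -> Layer:
    """Read a two/three-column directed edge list into a :class:`Layer`.

    Lines are ``src dst [weight]`` (tab or whitespace separated); the
    optional weight column is ignored.  Duplicate lines collapse to a
    single edge; ``#`` comment lines are skipped.  An empty file yields
    an empty layer with a warning.
    """
    path = Path(path)
    edges: set[Edge] = set()
    for lineno, tokens in _tokenize(path):
        if len(tokens) < 2:
            raise ParseError(f"{path}:{lineno}: expected >=2 columns, got {len(tokens)}")
        edges.add((tokens[0], tokens[1]))
    if not edges:
        warnings.warn(f"{path}: empty edge list; returning an empty layer", stacklevel=2)
    return Layer.from_edges(edges, layer_id=layer_id)


def read_multiplex(path: str | Path) -> MultilayerNetwork:
    """Read a multiplex extended edge list (``layer src dst weight``).

    Layer ids must be positive integers; layers are ordered ascending
    (layer 1 becomes the default reference layer).  Every layer's node
    set is expanded to the union universe, so nodes absent from one
    layer's raw lines appear there as isolated nodes.
    """
    path = Path(path)
    per_layer: dict[int, set[Edge]] = {}
    for lineno, tokens in _tokenize(path):
        if len(tokens) != 4:
            raise ParseError(f"{path}:{lineno}: expected 4 columns, got {len(tokens)}")
        try:
            lid = int(tokens[0])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer layer id {tokens[0]!r}") from exc
        if lid < 1:
            raise ParseError(f"{path}:{lineno}: layer id must be positive, got {lid}")
        per_layer.setdefault(lid, set()).add((tokens[1], tokens[2]))
    if not per_layer:
        raise ParseError(f"{path}: no edges found")
    layers = [
        Layer.from_edges(per_layer[lid], layer_id=str(lid)) for lid in sorted(per_layer)
    ]
    return MultilayerNetwork.from_layers(layers)


def read_node_weights(path: str | Path) -> FunctionWeights:
    """Read a two-column ``node weight`` table of function weights."""
    path = Path(path)
    weights: dict[NodeId, float] = {}
    for lineno, tokens in _tokenize(path):
        if len(tokens) < 2:
            raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(tokens)}")
        try:
            w = float(tokens[1])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric weight {tokens[1]!r}") from exc
        if w < 0:
            raise ParseError(f"{path}:{lineno}: negative weight {w} for node {tokens[0]!r}")
        weights[tokens[0]] = w
    return FunctionWeights(weights)


def validate_network(net: MultilayerNetwork) -> dict:
    """Report-only sanity summary of a multilayer network.

    Returns per-layer node/edge/self-loop counts and, for each layer,
    the nodes of the shared universe that none of its edges touch
    (isolated nodes introduced by universe expansion).  Never raises.
    """
    report: dict = {
        "n_layers": net.S,
        "n_nodes": net.N,
        "shared_universe_ok": True,
        "layers": [],
    }
    for lay in net.layers:
        touched = {n for e in lay.edges for n in e}
        report["layers"].append(
            {
                "layer_id": lay.layer_id,
                "n_nodes": lay.n_nodes,
                "n_edges": lay.n_edges,
                "n_self_loops": len(lay.self_loops),
                "isolated_nodes": sorted(lay.nodes - touched),
            }
        )
    any_isolated = any(l["isolated_nodes"] for l in report["layers"])
    report["universe_expanded"] = any_isolated
    return report


def write_edge_list(layer: Layer, path: str | Path) -> None:
    """Write a layer as a sorted two-column edge list (byte-stable)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in sorted(layer.edges):
            fh.write(f"{u}\t{v}\n")


def write_multiplex(net: MultilayerNetwork, path: str | Path) -> None:
    """Write a network in the multiplex extended edge-list dialect.

    Layer ids are re-numbered 1..S in order; weights are written as 1.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for idx, lay in enumerate(net.layers, start=1):
            for u, v in sorted(lay.edges):
                fh.write(f"{idx} {u} {v} 1\n")
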