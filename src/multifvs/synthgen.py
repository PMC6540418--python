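"""Synthetic multilayer networks and the worked-example duplex fixture.

Everything the test-suite and demos need is generated here, so no
network downloads are required: the seven-node duplex whose published
cycle structure exercises every step of the greedy solver, random
correlated duplex/multilayer ensembles, and an on-disk fixture suite in
both supported text formats.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .cycle_analysis import enumerate_cycles
from .fvs_core import sg_mfvs
from .multilayer_graph import (
    Layer,
    MultilayerNetwork,
    write_edge_list,
    write_multiplex,
)

#: Study layer of the worked duplex example.  Its simple cycles are
#: exactly: the self-loop at 2, a 3-cycle on {1,2,5}, a 4-cycle on
#: {2,3,4,5}, a 3-cycle on {1,5,7} and a 2-cycle on {3,4}; node 6 is
#: isolated.  Verified exhaustively at construction.
_STUDY_EDGES = [
    ("2", "2"),
    ("1", "2"),
    ("2", "5"),
    ("5", "1"),
    ("5", "4"),
    ("4", "3"),
    ("3", "2"),
    ("3", "4"),
    ("1", "7"),
    ("7", "5"),
]

#: Reference layer: two cycle "flowers" — 1<->2 and 2<->3 sharing node 2,
#: 4<->5 and 5<->6 sharing node 5 — whose unique minimum FVS is {2, 5};
#: node 7 is isolated.
_REFERENCE_EDGES = [
    ("1", "2"),
    ("2", "1"),
    ("2", "3"),
    ("3", "2"),
    ("4", "5"),
    ("5", "4"),
    ("5", "6"),
    ("6", "5"),
]

_UNIVERSE = [str(i) for i in range(1, 8)]

_STUDY_CYCLE_SETS = frozenset(
    {
        frozenset({"2"}),
        frozenset({"1", "2", "5"}),
        frozenset({"2", "3", "4", "5"}),
        frozenset({"1", "5", "7"}),
        frozenset({"3", "4"}),
    }
)


def worked_example_fixture() -> tuple[Layer, Layer]:
    """The worked-example duplex: (reference, study) layers on nodes 1–7.

    Construction is self-checking: the study layer must contain exactly
    the five published simple cycles and no others, and the reference
    layer's exact MFVS must be {2, 5}.
    """
    reference = Layer.from_edges(_REFERENCE_EDGES, layer_id="reference", extra_nodes=_UNIVERSE)
    study = Layer.from_edges(_STUDY_EDGES, layer_id="study", extra_nodes=_UNIVERSE)
    found = frozenset(frozenset(c) for c in enumerate_cycles(study).cycles)
    if found != _STUDY_CYCLE_SETS:
        raise RuntimeError(
            f"worked-example study layer inconsistent: cycles {sorted(map(sorted, found))}"
        )
    ref_fvs = sg_mfvs(reference).fvs
    if ref_fvs != frozenset({"2", "5"}):
        raise RuntimeError(
            f"worked-example reference layer inconsistent: MFVS {sorted(ref_fvs)}"
        )
    return reference, study


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the random correlated multilayer ensemble.

    ``layer_correlation`` is the probability that a node pair's
    presence/absence is copied from a shared base draw rather than
    redrawn independently per layer, giving partially overlapping
    layers as in real regulatory multiplexes.  ``edges_per_layer``
    switches to exact per-layer edge counts (shared fraction ≈
    ``layer_correlation``) instead of the Bernoulli model.
    """

    n: int = 10
    edge_prob: float = 0.2
    S: int = 2
    layer_correlation: float = 0.3
    self_loop_prob: float = 0.0
    seed: int = 0
    edges_per_layer: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        for name in ("edge_prob", "layer_correlation", "self_loop_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.n < 1 or self.S < 1:
            raise ValueError("n and S must be >= 1")
        if self.edges_per_layer is not None:
            if len(self.edges_per_layer) != self.S:
                raise ValueError("edges_per_layer must list one count per layer")
            if max(self.edges_per_layer) > self.n * (self.n - 1):
                raise ValueError("edge count exceeds number of ordered node pairs")


def _node_ids(n: int) -> list[str]:
    width = len(str(n))
    return [f"n{i:0{width}d}" for i in range(1, n + 1)]


def random_multilayer(spec: GeneratorSpec) -> MultilayerNetwork:
    """Random directed multilayer network, reproducible from the seed."""
    rng = np.random.default_rng(spec.seed)
    ids = _node_ids(spec.n)
    pairs = [(u, v) for u in ids for v in ids if u != v]
    layers = []
    if spec.edges_per_layer is not None:
        n_shared = round(spec.layer_correlation * min(spec.edges_per_layer))
        perm = rng.permutation(len(pairs))
        shared = [pairs[i] for i in perm[:n_shared]]
        remaining = [pairs[i] for i in perm[n_shared:]]
        for k, m in enumerate(spec.edges_per_layer):
            extra_idx = rng.choice(len(remaining), size=m - n_shared, replace=False)
            edges = shared + [remaining[i] for i in sorted(extra_idx)]
            layers.append(
                Layer.from_edges(edges, layer_id=str(k + 1), extra_nodes=ids)
            )
    else:
        base = rng.random(len(pairs)) < spec.edge_prob
        for k in range(spec.S):
            copy_base = rng.random(len(pairs)) < spec.layer_correlation
            fresh = rng.random(len(pairs)) < spec.edge_prob
            present = np.where(copy_base, base, fresh)
            edges = [p for p, keep in zip(pairs, present) if keep]
            if spec.self_loop_prob > 0:
                loops = rng.random(len(ids)) < spec.self_loop_prob
                edges += [(u, u) for u, keep in zip(ids, loops) if keep]
            layers.append(
                Layer.from_edges(edges, layer_id=str(k + 1), extra_nodes=ids)
            )
    return MultilayerNetwork.from_layers(layers)


def cicc_shaped_duplex(seed: int = 0) -> MultilayerNetwork:
    """A 14-node duplex with 38 and 42 directed links per layer — the
    shape of a published cancer–immune cell–cell duplex (topology is
    synthetic; only the sizes match)."""
    return random_multilayer(
        GeneratorSpec(n=14, S=2, layer_correlation=0.3, seed=seed,
                      edges_per_layer=(38, 42))
    )


def write_fixture_suite(directory: str | Path) -> dict:
    """Write the fixture networks to ``directory`` and return a manifest.

    Emits the worked-example duplex (edge lists and multiplex format),
    two small oracle-verified instances, and a 14-node duplex shaped
    like the published cancer–immune network.  Output is byte-stable:
    re-running overwrites identically.
    """
    from .iisg_solver import min_union_oracle  # local import: avoids cycle

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    reference, study = worked_example_fixture()
    write_edge_list(reference, directory / "worked_reference.tsv")
    write_edge_list(study, directory / "worked_study.tsv")
    duplex = MultilayerNetwork((reference, study))
    write_multiplex(duplex, directory / "worked_duplex.edges")

    shared_tri = MultilayerNetwork.from_layers(
        [
            Layer.from_edges([("a", "b"), ("b", "c"), ("c", "a")], layer_id="1"),
            Layer.from_edges([("a", "c"), ("c", "b"), ("b", "a")], layer_id="2"),
        ]
    )
    disjoint = MultilayerNetwork.from_layers(
        [
            Layer.from_edges([("a", "b"), ("b", "a")], layer_id="1",
                             extra_nodes=["c", "d"]),
            Layer.from_edges([("c", "d"), ("d", "c")], layer_id="2",
                             extra_nodes=["a", "b"]),
        ]
    )
    cicc = cicc_shaped_duplex(seed=0)
    write_multiplex(shared_tri, directory / "shared_triangle.edges")
    write_multiplex(disjoint, directory / "disjoint_2cycles.edges")
    write_multiplex(cicc, directory / "cicc_shaped.edges")

    manifest = {
        "instances": [
            {
                "name": "worked_duplex",
                "files": ["worked_reference.tsv", "worked_study.tsv", "worked_duplex.edges"],
                "expected": {"reference_mfvs_size": 2, "min_union_size": 3},
            },
            {
                "name": "shared_triangle",
                "files": ["shared_triangle.edges"],
                "expected": {"min_union_size": min_union_oracle(shared_tri).size},
            },
            {
                "name": "disjoint_2cycles",
                "files": ["disjoint_2cycles.edges"],
                "expected": {"min_union_size": min_union_oracle(disjoint).size},
            },
            {
                "name": "cicc_shaped",
                "files": ["cicc_shaped.edges"],
                "expected": {
                    "n_nodes": 14,
                    "edges_per_layer": [38, 42],
                    "min_union_size": min_union_oracle(cicc).size,
                },
            },
        ]
    }
    with open(directory / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest
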