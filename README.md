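# multifvs

Driver-node identification for nonlinear multilayer networks via the
minimum feedback-vertex-set union problem.

## The problem

Many biological systems — signalling networks, host–pathogen protein
interactions, cell–cell communication — are naturally *multilayer*: one
fixed set of nodes (genes, proteins, cell types) connected by several
directed interaction types at once. Controlling such a system means
choosing *driver nodes* whose states, when externally overridden, steer
the nonlinear dynamics from any initial condition into a desired
attractor of every layer.

For single directed networks with decay-type nonlinear dynamics, a
**feedback vertex set** (FVS) — a node set whose removal leaves the
graph acyclic — is a sufficient driver set: clamping the FVS to its
values on a target attractor leaves an acyclic free subsystem whose
states are slaved, node by node, to already-converged inputs. Under the
assumption that a node is a driver in every layer or in none, the
minimal driver set of an S-layer network `G^(1), …, G^(S)` solves

```
min |F_1 ∪ F_2 ∪ … ∪ F_S|,   F_a an FVS of layer a.
```

`multifvs` implements three solvers for this union problem, an exact
single-layer core, a dynamics simulator that validates the control
claim, and synthetic generators so everything is testable offline:

| piece | what it does |
|---|---|
| **SG** | exact single-layer MFVS: reductions (self-loop forcing, degree-0 pruning, degree-1 contraction) + branch-and-bound over SCCs |
| **ISG** | baseline: union of independently solved per-layer MFVSs |
| **IISG** | greedy improvement: solve the *reference layer* exactly, then cover each *study layer's* cycles preferring *dominated nodes* — nodes already in the reference FVS, on many passing loops, or with larger function weight — so layers share drivers and the union shrinks |
| oracles | brute-force MFVS and minimum-union enumeration for testing |
| `control_sim` | decay + saturating-coupling ODEs per layer (`ẋ = F(x) + Bu`); attractor finding and driver-clamping validation |
| `synthgen` | the seven-node worked-example duplex, random correlated multilayer ensembles, on-disk fixture suites |

## Worked example

The bundled duplex has a reference layer whose unique MFVS is nodes
`{2, 5}` and a study layer with five simple cycles: a self-loop at 2,
3-cycles on `{1,2,5}` and `{1,5,7}`, a 4-cycle on `{2,3,4,5}` and a
2-cycle on `{3,4}`.

```bash
multifvs synth --preset worked_example --out fixtures
multifvs iisg --multiplex fixtures/worked_duplex.edges
```

```
# size=3 method=IISG valid_per_layer=True,True
2
3
5
```

IISG first adopts nodes 2 and 5 — each lies on three of the four study
cycles that touch the reference FVS, and both are reference-FVS members —
then one residual cycle on `{3,4}` remains and node 3 is taken by the
deterministic tie-break. The driver set `{2, 3, 5}` is a valid FVS of
both layers, and of minimum possible union size. The comparison table
shows why the greedy pays off:

```bash
multifvs compare --multiplex fixtures/worked_duplex.edges
```

```
method	size	drivers	valid_layer_1	valid_layer_2
SG(layer 1)	2	2,5	True	False
SG(layer 2)	3	2,4,7	False	True
ISG	4	2,4,5,7	True	True
IISG	3	2,3,5	True	True
oracle	3	2,3,5	True	True
```

The per-layer optima don't overlap well, so their union (ISG) has four
nodes; reusing the reference FVS inside the study layer (IISG) recovers
the true minimum of three.

As a library:

```python
from multifvs import worked_example_fixture, iisg_duplex

reference, study = worked_example_fixture()
result = iisg_duplex(reference, study)
print(sorted(result.driver_nodes), result.size, result.all_valid)
# ['2', '3', '5'] 3 True
```

Control validation clamps a driver set to a target attractor of the
simulated nonlinear dynamics and reports convergence rates per seed:

```bash
multifvs iisg --multiplex fixtures/worked_duplex.edges --out drivers.txt
multifvs validate-control --multiplex fixtures/worked_duplex.edges \
    --drivers drivers.txt --seeds 5 --trials 20
```

## Running on real multiplex data

Published analyses of this method used curated regulatory and
host–pathogen networks that must be obtained from their sources (KEGG,
BioGRID, the CoMuNe lab multiplex repository, literature curation) and
are not redistributed here. Once you have a file in either supported
dialect —

* per-layer edge lists `src<TAB>dst[<TAB>weight]`, one file per layer, or
* a multiplex extended edge list `layer src dst weight` (CoMuNe dialect) —

the same commands apply directly, e.g.
`multifvs iisg --multiplex HIV1_gpi.edges --reference 1` or
`multifvs compare --multiplex cicc.edges --weights functions.tsv`,
where the optional weight table supplies the "function weight" used as
the third dominated-node ranking criterion.

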