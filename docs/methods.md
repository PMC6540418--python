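# Methods

## Model

A multilayer (multiplex) network is a fixed node universe of size N
connected by S ordered directed layers, each one interaction type. Its
dynamics are modelled per layer as ordinary differential equations

    ẋ(t) = F(x) + B u(t),

where the state x stacks one length-N vector per layer, F is a
continuously differentiable per-layer drift, and B is a block-diagonal
0/1 control matrix selecting the *same* driver-node positions in every
layer — the working assumption throughout is that a node is a driver in
all layers or in none. Controlling the system means choosing the
fewest driver nodes such that overriding their states steers each
layer's dynamics into any desired attractor.

For decay-type nonlinear dynamics, a feedback vertex set (FVS) of a
layer is a sufficient driver set for that layer: once the FVS is held
on a target trajectory, the remaining subgraph is acyclic, and each
free node's state relaxes to the value dictated by its (already
converged) upstream inputs. The multilayer driver problem is therefore
the minimum FVS *union* problem

    min |F_1 ∪ F_2 ∪ … ∪ F_S|,  F_a an FVS of layer a,

which this package solves exactly on small instances (oracle) and
heuristically at scale (ISG baseline, IISG greedy).

## Single-layer core (SG)

`simplify` applies three standard FVS-preserving reductions to a
fixpoint, scanning nodes in sorted order so the outcome is
deterministic:

* **R1** a node with a self-loop is in every FVS: record as forced,
  delete;
* **R2** a node with in-degree 0 or out-degree 0 lies on no cycle:
  delete;
* **R3** a node with in-degree 1 (out-degree 1) and no self-loop is
  contracted into its sole predecessor (successor): every cycle through
  it passes the neighbour, so the neighbour dominates it. Contractions
  keep the surviving neighbour's identity, so forced ∪ MFVS(residual)
  is already a node set of the original graph, and
  |MFVS(original)| = |forced| + |MFVS(residual)|.

`exact_mfvs` then decomposes the residual into strongly connected
components and solves each by branch-and-bound: branch over the
vertices of a shortest cycle (every FVS contains at least one), re-apply
the reductions in each subproblem, and prune with the incumbent plus a
greedy vertex-disjoint-cycle-packing lower bound. Exactness is
property-tested against an independent subset-enumeration oracle on
hundreds of random digraphs.

Tie-breaking: all scans and branches run in sorted node order and
equal-size candidates are compared as sorted tuples, so identical
inputs give identical outputs. Because R3 contractions collapse
equivalent optima, the returned set is the deterministic preferred
representative, not necessarily the globally lexicographically smallest
optimum; the contract is validity and minimality of size.

Budget: exact search refuses a residual SCC above `node_budget`
(default 40 nodes). Regulatory networks reduce far below this; for
pathological inputs the error message points to the greedy fallback.

## Cycle analysis

Dominated-node ranking needs, for candidate nodes, the number of
"passing loops" — directed simple cycles of the study layer through
them. Enumeration uses SCC-restricted backtracking (Johnson's
algorithm via networkx), canonicalises each cycle to the rotation
starting at its smallest node id (direction is preserved; no
reflection), and sorts by (length, sequence) for determinism. A
self-loop is a cycle of length 1.

Exhaustive enumeration is exponential in general, so it stops at
`cycle_cap` (default 100 000) and flags truncation, in which case the
solver re-counts cycles up to `length_bound` (default 12) nodes.
The ranking only needs *relative* counts, so a consistent length-bounded
census preserves the greedy's behaviour in practice.

## Cross-layer solvers

**ISG.** Solve every layer exactly with SG and take the union. Valid
by construction, but per-layer optima chosen independently rarely
overlap, so the union is typically oversized. (The historical name
speaks of an intersection; an intersection of per-layer FVSs is in
general not an FVS of any layer, and the optimization model is
explicitly a minimum union, so the union is what is implemented.)

**IISG.** Solve the reference layer exactly (F_r), then for each study
layer build F_i greedily:

1. While some cycle of the study layer (minus the nodes already in
   F_i) passes through an unused reference node, rank the nodes on
   those reference-hitting cycles and commit the best one to F_i.
2. When no reference-hitting cycles remain, cover the residual cycles
   the same way until the layer is acyclic.
3. The driver set is F_r ∪ ⋃ F_i. For S > 2 the accumulated union
   plays the reference role for each subsequent layer.

*Dominated-node order.* Candidates are ranked lexicographically by
(reference-FVS membership, passing-loop count, function weight)
descending, with ascending node id as the final tie-break; the priority
of the three criteria is configurable. This order reproduces the
bundled worked example: nodes 2 and 5 are taken first (reference
members on the most loops) and node 3 is the deterministic choice from
the final residual 2-cycle. One node is committed per iteration and
loop counts are recomputed after each removal — batch selection risks
over-covering cycles that a single removal already breaks.

*Degenerate cases.* An acyclic reference layer has an empty FVS and
nothing to reuse, so the greedy degenerates to the exact single-layer
solver on each study layer. If the accumulated reference set touches
no cycle of the next layer, phase 1 is skipped entirely.

*`--exact-residual`.* Optionally replaces phase 2 with an exact solve
of the residual study graph. Often shrinks unions further; off by
default to match the plain greedy procedure.

IISG is a heuristic: it is always sound (the returned set is verified
as an FVS of every layer) and never beats the exact oracle, but carries
no approximation guarantee. On 200 random correlated duplexes it was
never larger than ISG (logged as a regression metric in the test
suite), mirroring the one-node reductions reported for real duplexes.

## Dynamics and control validation

The drift is instantiated in the class for which FVS clamping control
is established — linear decay plus bounded saturating coupling.
Within layer a,

    ẋ_i = −d·x_i + Σ_j w_ji · tanh(g·x_j),   j → i an edge of layer a.

Parameters (all dimensionless except d, in inverse time units):

| parameter | default | why |
|---|---|---|
| decay d | 1.0 | sets the relaxation timescale |
| coupling magnitudes | uniform on [0.75, 1.5] | with the default gain, w·g/d ≥ 1.5 on every edge — past the pitchfork threshold of a positive feedback loop, so cycles create multistability |
| gain g | 2.0 | see above |
| positive-weight probability | 0.9 | regulatory networks are activation-dominated; negative weights keep the ensemble from being purely cooperative |
| integration | RK45, rtol 1e−8, atol 1e−10, t_max 200, fixed-point tolerance ‖F(x)‖∞ < 1e−6 | fixed points of tanh-coupled decay systems are hyperbolic for generic weights; chunked integration stops early at convergence and flags divergence past ‖x‖∞ = 1e3 |
| attractor identity | L∞ distance < 1e−3 | two converged states closer than this count as the same attractor |

Validation clamps the driver set as a hard state override (the B·u
channel is represented for completeness, but the FVS control principle
is stated for overrides): driver coordinates are pinned to their target
values in every layer and only free coordinates are integrated.
Success means the final state is within the attractor-identity
tolerance of the target on all S·N coordinates. When the clamped set
is an FVS of every layer the free subsystem is acyclic, and because
each free node has strict self-decay and bounded inputs, convergence is
global — the observed 100% success rate over the test ensemble is the
theory working as stated, not a tuned outcome. Clamping nothing from
the wrong basin of a bistable system fails, which is the negative
control.

## Synthetic data

`worked_example_fixture` reconstructs the published worked-example duplex from
its cycle structure rather than an edge list (which was never printed):
edge orientations were chosen so the study layer's simple cycles are
exactly the self-loop at 2, 3-cycles on {1,2,5} and {1,5,7}, the
4-cycle on {2,3,4,5}, and the 2-cycle on {3,4} — the last is required
for exactly one circle to survive the removal of the reference FVS
{2,5}. The construction re-enumerates its own cycles and re-solves the
reference layer at build time and refuses to return an inconsistent
fixture. Any realization with this cycle structure reproduces the
worked example, because FVS computations depend only on cycle
structure.

`random_multilayer` draws correlated directed Erdős–Rényi layers: each
ordered pair copies a shared base draw with probability
`layer_correlation` (default 0.3, mimicking partially overlapping
biological layers) and is redrawn independently otherwise; an
alternative mode fixes exact per-layer edge counts (used for a
14-node, 38/42-edge duplex shaped like a published cancer–immune
network). What the ensemble does *not* emulate: scale-free degree
structure, motif enrichment, signed/annotated interactions, or the
actual topologies of curated networks — so passing tests demonstrate
algorithmic correctness and the control principle on generic sparse
digraphs, not biological conclusions about any real system.

Test problem sizes — random digraphs of 5–12 nodes at densities
0.1–0.5 (200 instances for solver-vs-oracle equivalence), 200 random
duplexes of 5–12 nodes for union soundness, and 10 six-node duplex
topologies × 2 multistable dynamics realisations × 5 initial states
for control validation — were chosen so the brute-force oracles remain
exact references while covering the density range where FVS structure
varies most.

## Known limitations

* Exact search is exponential; the per-SCC budget makes the failure
  mode explicit rather than open-ended.
* IISG has no approximation ratio; the fold order (reference first,
  then file order) can change the result's membership, though never
  its validity.
* Cycle-capped ranking can in principle reorder greedy picks on graphs
  with more than `cycle_cap` simple cycles.
* The dynamics module validates the control principle for one
  decay-saturation family; it is a faithfulness check of the FVS
  theory, not a biophysical model of any particular system.
* Only topology is used: multiplex edge weights are parsed and
  discarded, and node function weights enter solely as a ranking
  tie-break.
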