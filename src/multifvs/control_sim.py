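"""Nonlinear multilayer dynamics and FVS-clamping control validation.

The network dynamics follow the decay-plus-saturating-coupling class
for which feedback-vertex-set control is established: node i of layer
a evolves as

    dx_i/dt = -d * x_i + sum_j  w_ji * sigma(x_j)      (within layer a)

with d > 0 a linear decay rate, w_ji a signed coupling weight on each
directed edge j -> i of that layer, and sigma(x) = tanh(g * x) a bounded
sigmoid of gain g.  Layers share nodes but evolve on separate state
copies; the external-control term B u(t) enters at the same (driver)
node positions in every layer.  With coupling magnitudes and gain
above the pitchfork threshold (w * g > d on a positive feedback loop)
the system is multistable, which is what makes control non-trivial.

Control is validated by *clamping*: the driver nodes' states are
overridden to their values in a target attractor in every layer, and
the remaining coordinates are integrated.  When the clamped set is an
FVS of every layer the free subsystem is acyclic, so each free node's
state is slaved to already-converged inputs and the whole system
settles into the target attractor — the FVS control principle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .multilayer_graph import Layer, MultilayerNetwork, NodeId

#: L-infinity distance under which two converged states count as the
#: same attractor.
ATTRACTOR_TOL = 1e-3

#: State-norm bound beyond which an integration is flagged divergent.
DIVERGENCE_BOUND = 1e3


@dataclass(frozen=True)
class CouplingParams:
    """Parameters of the decay + saturating-coupling vector field.

    decay
        Linear self-decay rate d (time^-1); must be positive.
    coupling_range
        (low, high) magnitudes for the uniform draw of |w| per edge.
    gain
        Sigmoid gain g in sigma(x) = tanh(g x).  With the defaults,
        w*g/d >= 1.5 on every edge, past the bistability threshold of
        a positive 2-cycle.
    positive_prob
        Probability that an edge weight is positive (activating).
    """

    decay: float = 1.0
    coupling_range: tuple[float, float] = (0.75, 1.5)
    gain: float = 2.0
    positive_prob: float = 0.9

    def __post_init__(self) -> None:
        if self.decay <= 0:
            raise ValueError(f"decay must be positive, got {self.decay}")
        lo, hi = self.coupling_range
        if not 0 <= lo <= hi:
            raise ValueError("coupling_range must satisfy 0 <= low <= high")


@dataclass
class DynamicsModel:
    """Concrete nonlinear dynamics on a multilayer network.

    State is a flat vector of length S*N ordered layer-major; node
    order within a layer is ``node_order`` (sorted universe).
    ``weights[a]`` is the N x N matrix with entry (i, j) the signed
    weight of edge j -> i in layer a (zero where no edge).
    """

    net: MultilayerNetwork
    params: CouplingParams
    seed: int
    node_order: tuple[NodeId, ...]
    weights: list[np.ndarray]

    @property
    def dim(self) -> int:
        return self.net.S * self.net.N

    def index_of(self, node: NodeId, layer: int) -> int:
        return layer * self.net.N + self.node_order.index(node)

    def rhs(self, x: np.ndarray) -> np.ndarray:
        """The drift F(x) (no external input)."""
        S, N = self.net.S, self.net.N
        xs = x.reshape(S, N)
        sig = np.tanh(self.params.gain * xs)
        out = -self.params.decay * xs
        for a in range(S):
            out[a] += self.weights[a] @ sig[a]
        return out.ravel()

    def control_matrix(self, drivers: Iterable[NodeId]) -> np.ndarray:
        """0/1 node-selection control matrix B = diag(B^(1),...,B^(S)).

        Each layer block is N x P with one nonzero per column, P the
        number of driver nodes — the same positions in every layer.
        """
        drv = sorted(set(drivers))
        S, N, P = self.net.S, self.net.N, len(drv)
        B = np.zeros((S * N, S * P))
        for a in range(S):
            for k, node in enumerate(drv):
                B[a * N + self.node_order.index(node), a * P + k] = 1.0
        return B


@dataclass(frozen=True)
class Attractor:
    """A fixed point located by forward integration."""

    state: np.ndarray
    residual_norm: float
    converged: bool

    def per_layer(self, net: MultilayerNetwork) -> np.ndarray:
        return self.state.reshape(net.S, net.N)


@dataclass(frozen=True)
class Trajectory:
    """Outcome of a clamped simulation."""

    t: np.ndarray
    states: np.ndarray  # shape (len(t), dim)
    success: bool
    final_state: np.ndarray


def build_dynamics(
    net: MultilayerNetwork,
    params: CouplingParams | None = None,
    seed: int = 0,
) -> DynamicsModel:
    """Draw reproducible signed edge weights and assemble the model.

    Weight magnitudes are uniform on ``params.coupling_range`` and
    signs are positive with probability ``params.positive_prob``;
    identical seeds give identical weights.
    """
    if params is None:
        params = CouplingParams()
    rng = np.random.default_rng(seed)
    order = tuple(sorted(net.node_universe))
    pos = {n: i for i, n in enumerate(order)}
    weights = []
    for lay in net.layers:
        W = np.zeros((net.N, net.N))
        for u, v in sorted(lay.edges):
            mag = rng.uniform(*params.coupling_range)
            sign = 1.0 if rng.random() < params.positive_prob else -1.0
            W[pos[v], pos[u]] = sign * mag
        weights.append(W)
    return DynamicsModel(
        net=net, params=params, seed=seed, node_order=order, weights=weights
    )


def _integrate(
    rhs: Callable[[np.ndarray], np.ndarray],
    x0: np.ndarray,
    t_max: float,
    tol: float,
    n_chunks: int = 20,
    max_step: float = np.inf,
):
    """Integrate in chunks, stopping early at a fixed point or on
    divergence.  Returns (t, states, converged, residual)."""
    x = np.asarray(x0, dtype=float).copy()
    ts = [0.0]
    states = [x.copy()]
    chunk = t_max / n_chunks
    converged = np.max(np.abs(rhs(x))) < tol
    for k in range(n_chunks):
        if converged:
            break
        sol = solve_ivp(
            lambda t, y: rhs(y),
            (k * chunk, (k + 1) * chunk),
            x,
            method="RK45",
            rtol=1e-8,
            atol=1e-10,
            max_step=max_step,
        )
        x = sol.y[:, -1]
        ts.extend(sol.t[1:].tolist())
        states.extend(sol.y[:, 1:].T)
        if np.max(np.abs(x)) > DIVERGENCE_BOUND:
            break
        converged = np.max(np.abs(rhs(x))) < tol
    residual = float(np.max(np.abs(rhs(x))))
    return np.array(ts), np.array(states), converged, residual


def find_attractor(
    model: DynamicsModel,
    init: np.ndarray,
    t_max: float = 200.0,
    tol: float = 1e-6,
) -> Attractor:
    """Integrate the free dynamics (u = 0) from ``init`` until the
    drift's L-infinity norm falls below ``tol`` or time runs out."""
    if tol <= 0:
        raise ValueError("tol must be positive")
    _, states, converged, residual = _integrate(model.rhs, init, t_max, tol)
    return Attractor(state=states[-1], residual_norm=residual, converged=converged)


def clamp_and_simulate(
    model: DynamicsModel,
    drivers: Iterable[NodeId],
    target: Attractor,
    init: np.ndarray,
    t_max: float = 200.0,
    tol: float = 1e-6,
    success_tol: float = ATTRACTOR_TOL,
) -> Trajectory:
    """Clamp the driver nodes to their target values and integrate.

    Driver coordinates are hard-overridden (state held constant) at
    the target attractor's values *in every layer*; free coordinates
    follow the drift.  Success means the final state is within
    ``success_tol`` of the target on all S*N coordinates.
    """
    if not target.converged:
        raise ValueError("target must be a converged attractor")
    drv = set(drivers)
    unknown = drv - set(model.node_order)
    if unknown:
        raise KeyError(f"unknown driver nodes: {sorted(unknown)}")
    clamped = np.zeros(model.dim, dtype=bool)
    for a in range(model.net.S):
        for node in drv:
            clamped[model.index_of(node, a)] = True

    def rhs(x: np.ndarray) -> np.ndarray:
        dx = model.rhs(x)
        dx[clamped] = 0.0
        return dx

    x0 = np.asarray(init, dtype=float).copy()
    x0[clamped] = target.state[clamped]
    t, states, _, _ = _integrate(rhs, x0, t_max, tol)
    final = states[-1]
    success = bool(np.max(np.abs(final - target.state)) < success_tol)
    return Trajectory(t=t, states=states, success=success, final_state=final)


def sample_attractors(
    model: DynamicsModel,
    n_inits: int = 10,
    seed: int = 0,
    init_scale: float = 2.0,
    t_max: float = 200.0,
    tol: float = 1e-6,
) -> list[Attractor]:
    """Probe the attractor landscape from random initial states.

    Returns the distinct converged fixed points found (distinct under
    the L-infinity attractor-identity tolerance), in discovery order.
    """
    rng = np.random.default_rng(seed)
    found: list[Attractor] = []
    for _ in range(n_inits):
        x0 = rng.uniform(-init_scale, init_scale, size=model.dim)
        att = find_attractor(model, x0, t_max=t_max, tol=tol)
        if not att.converged:
            continue
        if all(
            np.max(np.abs(att.state - other.state)) > ATTRACTOR_TOL
            for other in found
        ):
            found.append(att)
    return found
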