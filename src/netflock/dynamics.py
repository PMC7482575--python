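"""Time-steppers for the two collective-motion models on a fixed network.

The Vicsek-Network (VN) model is a discrete-time heading-consensus rule:
each agent replaces its heading by the angle of the summed heading unit
vectors of itself and its network neighbours, plus uniform angular noise
``eta * xi`` with ``xi ~ U(-1/2, 1/2)``. Agent positions play no role.

The Active-Elastic (AE) model couples agents by linear springs whose rest
lengths are frozen at the initial inter-agent distances. The overdamped
equations of motion

    dx_i/dt     = v0 n_i + alpha (F_i . n_i) n_i
    dtheta_i/dt = beta (F_i . n_i_perp) + eta xi_i

are integrated by plain forward Euler with step ``dt``; ``n_i_perp`` is the
+90-degree rotation of the heading, so the torque steers an agent toward
the net spring force. Headings never propagate directly — only positions do.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .exceptions import (
    DegenerateGeometryError,
    InvalidInputError,
    InvalidSpecError,
    NumericalBlowupError,
)
from .network import InteractionNetwork

TWO_PI = 2.0 * np.pi


def wrap_angle(theta):
    """Wrap angles to the interval (-pi, pi]."""
    theta = np.asarray(theta, dtype=np.float64)
    w = (theta + np.pi) % TWO_PI - np.pi
    return np.where(w == -np.pi, np.pi, w)


# ---------------------------------------------------------------------------
# State and parameters
# ---------------------------------------------------------------------------


@dataclass
class SwarmState:
    """Positions and headings of every agent at one instant.

    ``positions`` is ``(N, 2)`` in lattice-spacing units (``None`` for the
    VN model, which never uses them); ``headings`` is ``(N,)`` in radians,
    wrapped to (-pi, pi]; ``time`` counts steps (VN) or continuous time (AE).
    """

    headings: np.ndarray
    positions: np.ndarray | None = None
    time: float = 0.0

    def __post_init__(self):
        self.headings = wrap_angle(np.asarray(self.headings, dtype=np.float64))
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=np.float64)
            if self.positions.shape != (self.headings.shape[0], 2):
                raise InvalidInputError("positions must be (N, 2) matching headings")

    @property
    def n_agents(self) -> int:
        return self.headings.shape[0]

    def heading_vectors(self) -> np.ndarray:
        """Unit vectors ``(cos theta, sin theta)`` per agent."""
        return np.column_stack([np.cos(self.headings), np.sin(self.headings)])

    def copy(self) -> "SwarmState":
        return SwarmState(
            self.headings.copy(),
            None if self.positions is None else self.positions.copy(),
            self.time,
        )


@dataclass(frozen=True)
class VNParams:
    """Vicsek-Network parameters: only the noise intensity ``eta``,
    from 0 (deterministic consensus) to 2*pi (fully random headings)."""

    eta: float

    def __post_init__(self):
        if not 0.0 <= self.eta <= TWO_PI:
            raise InvalidSpecError(f"eta must lie in [0, 2*pi], got {self.eta}")


@dataclass(frozen=True)
class AEParams:
    """Active-elastic parameters.

    Defaults are the reference working point known to self-organize quickly
    on lattice topologies: ``v0`` self-propulsion speed (lattice spacings
    per unit time), ``alpha`` force-to-speed and ``beta`` torque coupling,
    ``kappa`` spring constant (identical for every bond regardless of rest
    length), ``eta`` angular noise intensity and ``dt`` the Euler step.
    """

    eta: float
    v0: float = 0.002
    alpha: float = 0.01
    beta: float = 0.12
    kappa: float = 5.0
    dt: float = 0.1

    def __post_init__(self):
        if self.v0 <= 0 or self.kappa <= 0 or self.dt <= 0:
            raise InvalidSpecError("v0, kappa and dt must be positive")
        if self.alpha < 0 or self.beta < 0 or self.eta < 0:
            raise InvalidSpecError("alpha, beta and eta must be nonnegative")


# ---------------------------------------------------------------------------
# Initialisation
# ---------------------------------------------------------------------------


def init_aligned(positions, heading: float) -> SwarmState:
    """Fully aligned swarm (polarization exactly 1) at the given positions.

    ``positions`` may be ``None`` for VN runs, or an integer agent count.
    """
    if positions is None:
        raise InvalidInputError("pass an (N, 2) array or an agent count")
    if isinstance(positions, (int, np.integer)):
        n = int(positions)
        pos = None
    else:
        pos = np.asarray(positions, dtype=np.float64)
        n = pos.shape[0]
    return SwarmState(np.full(n, heading, dtype=np.float64), pos)


def assign_rest_lengths(
    network: InteractionNetwork, positions
) -> InteractionNetwork:
    """Freeze each bond's natural length to the current Euclidean distance
    between its endpoints (the t=0 configuration, so the initial state is
    stress-free)."""
    positions = np.asarray(positions, dtype=np.float64)
    if positions.shape != (network.n_nodes, 2):
        raise InvalidInputError("positions must be (N, 2) for every node")
    diffs = positions[network.edges[:, 1]] - positions[network.edges[:, 0]]
    dists = np.hypot(diffs[:, 0], diffs[:, 1])
    if np.any(dists == 0.0):
        bad = network.edges[dists == 0.0][0]
        raise DegenerateGeometryError(
            f"linked agents {bad[0]} and {bad[1]} coincide; spring length undefined"
        )
    return network.with_rest_lengths(dists)


# ---------------------------------------------------------------------------
# Single steps
# ---------------------------------------------------------------------------


def vn_step(
    state: SwarmState,
    network: InteractionNetwork,
    params: VNParams,
    rng: np.random.Generator,
) -> SwarmState:
    """One synchronous VN update (self included in each neighbourhood sum)."""
    if state.n_agents != network.n_nodes:
        raise InvalidInputError("state and network disagree on agent count")
    new = state.copy()
    indptr, indices = network.neighbor_lists()
    delta = params.eta * (rng.random((1, state.n_agents)) - 0.5)
    c, s = np.cos(new.headings), np.sin(new.headings)
    psi = np.empty(1)
    _kernels.vn_chunk(c, s, indptr, indices, delta, psi, 0)
    new.headings = wrap_angle(np.arctan2(s, c))
    new.time = state.time + 1
    return new


def ae_force(
    state: SwarmState, network: InteractionNetwork, params: AEParams
) -> np.ndarray:
    """Net linear-spring force on every agent, ``(N, 2)``.

    Bonds stretched beyond their rest length attract, compressed bonds
    repel; forces are equal and opposite within each pair. A coincident
    pair contributes nothing (direction undefined).
    """
    if network.rest_lengths is None:
        raise InvalidInputError("network has no rest lengths; call assign_rest_lengths")
    if state.positions is None:
        raise InvalidInputError("AE dynamics needs agent positions")
    i, j = network.edges[:, 0], network.edges[:, 1]
    d = state.positions[j] - state.positions[i]
    dist = np.hypot(d[:, 0], d[:, 1])
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(dist > 0, params.kappa * (dist - network.rest_lengths) / dist, 0.0)
    contrib = scale[:, None] * d
    forces = np.zeros((state.n_agents, 2))
    np.add.at(forces, i, contrib)
    np.add.at(forces, j, -contrib)
    return forces


def ae_step(
    state: SwarmState,
    network: InteractionNetwork,
    params: AEParams,
    rng: np.random.Generator,
) -> SwarmState:
    """One forward-Euler AE update (open boundary, positions unbounded)."""
    if state.positions is None:
        raise InvalidInputError("AE dynamics needs agent positions")
    if network.rest_lengths is None:
        raise InvalidInputError("network has no rest lengths; call assign_rest_lengths")
    if state.n_agents != network.n_nodes:
        raise InvalidInputError("state and network disagree on agent count")
    new = state.copy()
    x = np.ascontiguousarray(new.positions[:, 0])
    y = np.ascontiguousarray(new.positions[:, 1])
    noise = params.dt * params.eta * (rng.random((1, state.n_agents)) - 0.5)
    psi = np.empty(1)
    bad = _kernels.ae_chunk(
        x, y, new.headings,
        network.edges[:, 0], network.edges[:, 1], network.rest_lengths,
        params.v0, params.alpha, params.beta, params.kappa, params.dt,
        noise, psi, 0,
    )
    if bad >= 0:
        raise NumericalBlowupError("non-finite state after one AE step", step=int(state.time))
    new.positions = np.column_stack([x, y])
    new.time = state.time + params.dt
    return new


# ---------------------------------------------------------------------------
# Run loop
# ---------------------------------------------------------------------------


def run_model(
    model: str,
    network: InteractionNetwork,
    params,
    n_steps: int,
    seed=None,
    initial_state: SwarmState | None = None,
    rng: np.random.Generator | None = None,
    record_stride: int = 1,
) -> tuple[np.ndarray, SwarmState]:
    """Advance ``model`` (``"vn"`` or ``"ae"``) for ``n_steps`` and record
    the polarization after every step.

    Returns ``(psi, final_state)`` where ``psi[t]`` is the polarization
    after step ``t+1``, subsampled by ``record_stride``. Reproducible:
    the same seed yields a bitwise-identical series. Noise is drawn in
    step-sized blocks from a single ``numpy`` Generator, so chunked
    execution matches a loop of single steps draw for draw.
    """
    model = model.lower()
    if model not in ("vn", "ae"):
        raise InvalidSpecError(f"unknown model {model!r}")
    if rng is None:
        rng = np.random.default_rng(seed)
    state = initial_state.copy() if initial_state is not None else None
    if state is None:
        raise InvalidInputError("an initial state is required")
    if state.n_agents != network.n_nodes:
        raise InvalidInputError("state and network disagree on agent count")
    n = state.n_agents
    psi = np.empty(n_steps)
    chunk = max(1, min(n_steps, 4_000_000 // max(n, 1)))

    if model == "vn":
        if not isinstance(params, VNParams):
            params = VNParams(**params) if isinstance(params, dict) else params
        indptr, indices = network.neighbor_lists()
        c, s = np.cos(state.headings), np.sin(state.headings)
        done = 0
        while done < n_steps:
            m = min(chunk, n_steps - done)
            delta = params.eta * (rng.random((m, n)) - 0.5)
            _kernels.vn_chunk(c, s, indptr, indices, delta, psi, done)
            done += m
        state.headings = wrap_angle(np.arctan2(s, c))
        state.time += n_steps
    else:
        if network.rest_lengths is None:
            raise InvalidInputError("network has no rest lengths; call assign_rest_lengths")
        if state.positions is None:
            raise InvalidInputError("AE dynamics needs agent positions")
        x = np.ascontiguousarray(state.positions[:, 0])
        y = np.ascontiguousarray(state.positions[:, 1])
        ei = np.ascontiguousarray(network.edges[:, 0])
        ej = np.ascontiguousarray(network.edges[:, 1])
        done = 0
        while done < n_steps:
            m = min(chunk, n_steps - done)
            noise = params.dt * params.eta * (rng.random((m, n)) - 0.5)
            bad = _kernels.ae_chunk(
                x, y, state.headings, ei, ej, network.rest_lengths,
                params.v0, params.alpha, params.beta, params.kappa,
                params.dt, noise, psi, done,
            )
            if bad >= 0:
                raise NumericalBlowupError(
                    "non-finite state during AE integration", step=done + int(bad)
                )
            done += m
        state.positions = np.column_stack([x, y])
        state.time += n_steps * params.dt

    if record_stride > 1:
        psi = psi[record_stride - 1 :: record_stride]
    return psi, state
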