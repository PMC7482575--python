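"""Interaction-network generators.

Builds the three fixed interaction topologies used by the collective-motion
models — a Moore nearest-neighbour (NN) lattice network, Erdős–Rényi (ER)
random networks, and scale-free (SF) random networks with a prescribed,
integer-rounded power-law degree histogram — all conditioned on exact node
and edge counts, plus the superposition protocol that interpolates between
the lattice and a random network under a control parameter ``p``.

All generators are deterministic given a seed and guarantee a connected
simple graph (bounded retries, explicit failure).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .exceptions import (
    GenerationFailureError,
    InfeasibleTargetsError,
    InvalidInputError,
    InvalidSpecError,
)

log = logging.getLogger(__name__)

#: retry budget for connectivity-conditioned generators
MAX_RETRIES = 100


def _round_half_away(x: float) -> int:
    """Round to nearest integer, ties away from zero."""
    return int(np.sign(x) * np.floor(np.abs(x) + 0.5))


# ---------------------------------------------------------------------------
# Core containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LatticeSpec:
    """An ``L x L`` square lattice of agents with unit spacing.

    The lattice fixes both the agent count ``N = L**2`` and, through the
    Moore-neighbourhood construction, the edge count
    ``K = 2 (L - 1) (2 L - 1)`` shared by every topology compared against it.
    """

    L: int

    def __post_init__(self):
        if int(self.L) != self.L or self.L < 2:
            raise InvalidSpecError(f"lattice side must be an integer >= 2, got {self.L}")

    @property
    def n_nodes(self) -> int:
        return self.L * self.L

    @property
    def n_edges(self) -> int:
        return 2 * (self.L - 1) * (2 * self.L - 1)


class InteractionNetwork:
    """A fixed undirected simple graph over ``n_nodes`` agents.

    Edges are stored canonically as an ``(K, 2)`` integer array with
    ``i < j`` per row, rows lexicographically sorted. ``rest_lengths``,
    when present, is a per-edge array of natural spring lengths aligned
    with ``edges`` (units of the lattice spacing).
    """

    __slots__ = ("n_nodes", "edges", "rest_lengths", "_csr", "_nbr")

    def __init__(self, n_nodes: int, edges, rest_lengths=None):
        if n_nodes < 1:
            raise InvalidInputError("network needs at least one node")
        edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
        rest = None if rest_lengths is None else np.asarray(rest_lengths, dtype=np.float64)
        if rest is not None and rest.shape[0] != edges.shape[0]:
            raise InvalidInputError("rest_lengths must have one entry per edge")
        if edges.size:
            if edges.min() < 0 or edges.max() >= n_nodes:
                raise InvalidInputError("edge endpoint out of range")
            if np.any(edges[:, 0] == edges[:, 1]):
                raise InvalidInputError("self-loops are not allowed")
            lo = edges.min(axis=1)
            hi = edges.max(axis=1)
            edges = np.column_stack([lo, hi])
            order = np.lexsort((edges[:, 1], edges[:, 0]))
            edges = edges[order]
            if rest is not None:
                rest = rest[order]
                if np.any(rest <= 0):
                    raise InvalidInputError("rest lengths must be positive")
            dup = np.all(edges[1:] == edges[:-1], axis=1)
            if np.any(dup):
                raise InvalidInputError("duplicate edges are not allowed")
        self.n_nodes = int(n_nodes)
        self.edges = edges
        self.rest_lengths = rest
        self._csr = None
        self._nbr = None

    # -- basic queries ------------------------------------------------------

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        np.add.at(deg, self.edges.ravel(), 1)
        return deg

    def edge_set(self) -> set[tuple[int, int]]:
        return {(int(i), int(j)) for i, j in self.edges}

    def adjacency(self) -> csr_matrix:
        """Symmetric boolean adjacency as CSR (cached)."""
        if self._csr is None:
            i, j = self.edges[:, 0], self.edges[:, 1]
            data = np.ones(2 * self.n_edges, dtype=np.int8)
            self._csr = csr_matrix(
                (data, (np.concatenate([i, j]), np.concatenate([j, i]))),
                shape=(self.n_nodes, self.n_nodes),
            )
        return self._csr

    def neighbor_lists(self) -> tuple[np.ndarray, np.ndarray]:
        """CSR-style ``(indptr, indices)`` of neighbours, self excluded."""
        if self._nbr is None:
            a = self.adjacency()
            self._nbr = (a.indptr.astype(np.int64), a.indices.astype(np.int64))
        return self._nbr

    def with_rest_lengths(self, rest_lengths) -> "InteractionNetwork":
        return InteractionNetwork(self.n_nodes, self.edges.copy(), rest_lengths)

    def __eq__(self, other):
        return (
            isinstance(other, InteractionNetwork)
            and self.n_nodes == other.n_nodes
            and np.array_equal(self.edges, other.edges)
        )

    def __repr__(self):
        return f"InteractionNetwork(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


@dataclass
class DegreeSequence:
    """Integer node counts per degree: ``counts[k]`` nodes have degree ``k``."""

    counts: dict[int, int]

    def __post_init__(self):
        self.counts = {
            int(k): int(v) for k, v in sorted(self.counts.items()) if v != 0
        }
        if any(v < 0 for v in self.counts.values()) or any(
            k < 0 for k in self.counts
        ):
            raise InvalidInputError("degree-sequence counts must be nonnegative")

    @property
    def n_nodes(self) -> int:
        return sum(self.counts.values())

    @property
    def degree_sum(self) -> int:
        return sum(k * v for k, v in self.counts.items())

    @property
    def k_min(self) -> int:
        return min(self.counts)

    @property
    def k_max(self) -> int:
        return max(self.counts)

    def degree_list(self) -> np.ndarray:
        """Per-node target degrees, descending."""
        out = []
        for k in sorted(self.counts, reverse=True):
            out.extend([k] * self.counts[k])
        return np.array(out, dtype=np.int64)


@dataclass
class SFDegreeModel:
    """Specification (and solved state) of a truncated power-law degree
    histogram ``n_k = C k**b`` for ``k_min <= k <= k_max``.

    ``b < 0`` is the power-law exponent; ``W_N`` and ``W_K`` weight the
    squared node-count and edge-count errors in the objective
    ``J = W_N (N_opt - N_tgt)**2 + W_K (K_opt - K_tgt)**2`` minimised over
    the prefactor ``C`` and cutoff ``k_max``. After :func:`solve_sf_degree_sequence`
    the fields ``C``, ``k_max``, ``N_opt``, ``K_opt``, ``J`` and
    ``n_adjustments`` hold the optimum found.
    """

    N_tgt: int
    K_tgt: int
    b: float
    k_min: int = 2
    W_N: float = 10.0
    W_K: float = 1.0
    # populated by the solver
    C: float | None = None
    k_max: int | None = None
    N_opt: int | None = None
    K_opt: float | None = None
    J: float | None = None
    n_adjustments: int = 0
    adjustments: list = field(default_factory=list)

    def __post_init__(self):
        if self.b >= 0:
            raise InvalidSpecError("power-law exponent b must be negative")
        if self.k_min < 2:
            raise InvalidSpecError("k_min must be at least 2")
        if self.k_min >= self.N_tgt - 1:
            raise InvalidSpecError("k_min must be below N_tgt - 1")


# ---------------------------------------------------------------------------
# Connectivity
# ---------------------------------------------------------------------------


def is_connected(network: InteractionNetwork) -> bool:
    """True iff a single connected component spans all nodes."""
    if network.n_nodes == 1:
        return True
    if network.n_edges < network.n_nodes - 1:
        return False
    n_comp, _ = connected_components(network.adjacency(), directed=False)
    return n_comp == 1


def degree_histogram(network: InteractionNetwork) -> DegreeSequence:
    """Histogram of node degrees (includes isolated nodes as degree 0)."""
    deg = network.degrees()
    counts = np.bincount(deg)
    return DegreeSequence({k: int(c) for k, c in enumerate(counts) if c > 0})


# ---------------------------------------------------------------------------
# Nearest-neighbour lattice
# ---------------------------------------------------------------------------


def build_nn_lattice(spec: LatticeSpec | int):
    """Agents on an ``L x L`` unit lattice, each linked to its horizontal,
    vertical and diagonal first neighbours (Moore neighbourhood, no wrap).

    Returns ``(positions, network)`` where ``positions`` is an ``(N, 2)``
    float array in row-major node order (node ``r*L + c`` sits at
    ``(x, y) = (c, r)``). Corner nodes have degree 3, side nodes 5 and bulk
    nodes 8, for ``2 (L-1) (2L-1)`` edges in total.
    """
    if isinstance(spec, (int, np.integer)):
        spec = LatticeSpec(int(spec))
    L = spec.L
    r, c = np.divmod(np.arange(L * L, dtype=np.int64), L)
    positions = np.column_stack([c, r]).astype(np.float64)

    idx = np.arange(L * L, dtype=np.int64).reshape(L, L)
    pairs = [
        (idx[:, :-1], idx[:, 1:]),       # horizontal
        (idx[:-1, :], idx[1:, :]),       # vertical
        (idx[:-1, :-1], idx[1:, 1:]),    # diagonal down-right
        (idx[:-1, 1:], idx[1:, :-1]),    # diagonal down-left
    ]
    edges = np.concatenate(
        [np.column_stack([a.ravel(), b.ravel()]) for a, b in pairs]
    )
    network = InteractionNetwork(L * L, edges)
    assert network.n_edges == spec.n_edges
    return positions, network


# ---------------------------------------------------------------------------
# Erdős–Rényi with exact edge count
# ---------------------------------------------------------------------------


def _draw_er_edges(n_nodes: int, n_edges: int, rng: np.random.Generator) -> np.ndarray:
    """Accumulate distinct random pairs (rejecting self-pairs and repeats,
    first occurrence kept) until exactly ``n_edges`` links exist."""
    chosen = np.empty(0, dtype=np.int64)
    while chosen.size < n_edges:
        m = max(256, int(1.2 * (n_edges - chosen.size)))
        ii = rng.integers(0, n_nodes, size=m)
        jj = rng.integers(0, n_nodes, size=m)
        keep = ii != jj
        lo = np.minimum(ii, jj)[keep]
        hi = np.maximum(ii, jj)[keep]
        chosen = pd.unique(np.concatenate([chosen, lo * n_nodes + hi]))
    return chosen[:n_edges]


def build_er(
    n_nodes: int, n_edges: int, seed, max_retries: int = MAX_RETRIES
) -> InteractionNetwork:
    """Uniform random simple graph with exactly ``n_edges`` edges,
    conditioned on connectivity by regeneration with fresh draws."""
    max_possible = n_nodes * (n_nodes - 1) // 2
    if n_edges > max_possible:
        raise InvalidSpecError(
            f"{n_edges} edges impossible on {n_nodes} nodes (max {max_possible})"
        )
    if n_edges < n_nodes - 1:
        raise InvalidSpecError(
            f"{n_edges} edges cannot connect {n_nodes} nodes (need >= {n_nodes - 1})"
        )
    rng = np.random.default_rng(seed)
    for attempt in range(1, max_retries + 1):
        keys = _draw_er_edges(n_nodes, n_edges, rng)
        edges = np.column_stack(np.divmod(keys, n_nodes))
        net = InteractionNetwork(n_nodes, edges)
        if is_connected(net):
            if attempt > 1:
                log.debug("ER generator connected after %d attempts", attempt)
            return net
    raise GenerationFailureError(
        f"ER generator failed to produce a connected graph in {max_retries} attempts",
        attempts=max_retries,
    )


# ---------------------------------------------------------------------------
# Scale-free degree sequence: solve + realize
# ---------------------------------------------------------------------------


def _rounded_power_law(C: np.ndarray, kb: np.ndarray) -> np.ndarray:
    """Eq-style histogram: Round(C k^b) where C k^b >= 1, else 1.

    ``C`` is a vector of candidate prefactors, ``kb`` the vector ``k**b``;
    returns an ``(nC, nk)`` integer matrix. Rounding is half away from zero.
    """
    raw = C[:, None] * kb[None, :]
    rounded = np.floor(raw + 0.5)
    return np.where(raw >= 1.0, rounded, 1.0)


def solve_sf_degree_sequence(model: SFDegreeModel) -> DegreeSequence:
    """Find the integer degree histogram closest to a truncated power law
    that meets the node and edge targets exactly.

    Two stages. First, scan the integer cutoff ``k_max`` (ascending, ties to
    the smaller cutoff) and, per cutoff, numerically search the prefactor
    ``C`` minimising the weighted objective ``J``. Second, apply a
    deterministic integer adjustment: extend or trim the unit tail at the
    cutoff until the node count is exact, then shift single nodes one degree
    at a time (largest degree first) until the degree sum equals ``2 K_tgt``.
    The adjustment steps are recorded on ``model.adjustments``.
    """
    N_tgt, K_tgt, b, k_min = model.N_tgt, model.K_tgt, model.b, model.k_min
    target_sum = 2 * K_tgt
    if target_sum < k_min * N_tgt:
        raise InfeasibleTargetsError(
            f"degree sum {target_sum} below the k_min={k_min} floor for N={N_tgt}"
        )
    if K_tgt > N_tgt * (N_tgt - 1) // 2:
        raise InfeasibleTargetsError("more edges than a simple graph allows")

    best = None  # (J, k_max, C, N_opt, K_opt)
    for k_max in range(k_min + 1, N_tgt):
        ks = np.arange(k_min, k_max + 1, dtype=np.float64)
        # floor configuration (all n_k = 1) lower-bounds both totals
        floor_nodes = k_max - k_min + 1
        floor_sum = int(ks.sum())
        lb = model.W_N * max(0, floor_nodes - N_tgt) ** 2 + model.W_K * max(
            0.0, floor_sum / 2.0 - K_tgt
        ) ** 2
        if best is not None and lb > best[0]:
            break
        kb = ks**b
        C0 = max(N_tgt / kb.sum(), 1.0)
        Cs = np.geomspace(C0 / 8.0, C0 * 8.0, 241)
        for _refine in range(3):
            nk = _rounded_power_law(Cs, kb)
            N_opt = nk.sum(axis=1)
            K_opt = (nk * ks[None, :]).sum(axis=1) / 2.0
            J = model.W_N * (N_opt - N_tgt) ** 2 + model.W_K * (K_opt - K_tgt) ** 2
            i = int(np.argmin(J))
            Cbest, Jbest = Cs[i], J[i]
            Cs = np.geomspace(Cbest / 1.2, Cbest * 1.2, 241)
        if best is None or Jbest < best[0]:
            best = (Jbest, k_max, Cbest, int(N_opt[i]), float(K_opt[i]))
        if Jbest == 0.0:
            break

    if best is None:
        raise InfeasibleTargetsError("no feasible cutoff found")
    J, k_max, C, N_opt, K_opt = best
    model.J, model.k_max, model.C = float(J), int(k_max), float(C)
    model.N_opt, model.K_opt = N_opt, K_opt

    ks = np.arange(k_min, k_max + 1, dtype=np.float64)
    nk = _rounded_power_law(np.array([C]), ks**b)[0].astype(int)
    counts = {int(k): int(n) for k, n in zip(ks.astype(int), nk)}
    adjustments: list[str] = []

    # phase 1: exact node count via the unit tail at the cutoff
    def total():
        return sum(counts.values())

    while total() > N_tgt:
        kmx = max(k for k, v in counts.items() if v > 0)
        counts[kmx] -= 1
        adjustments.append(f"drop one node at k={kmx}")
    while total() < N_tgt:
        kmx = max(k for k, v in counts.items() if v > 0)
        if kmx + 1 > N_tgt - 1:
            raise InfeasibleTargetsError("cutoff would exceed N-1 during adjustment")
        counts[kmx + 1] = counts.get(kmx + 1, 0) + 1
        adjustments.append(f"add one node at k={kmx + 1}")

    # phase 2: exact degree sum by single-degree shifts, largest degree first
    def dsum():
        return sum(k * v for k, v in counts.items())

    while dsum() > target_sum:
        kmx = max(k for k, v in counts.items() if v > 0)
        if kmx - 1 < k_min:
            raise InfeasibleTargetsError("cannot reduce degree sum without breaking k_min")
        counts[kmx] -= 1
        counts[kmx - 1] = counts.get(kmx - 1, 0) + 1
        adjustments.append(f"move one node k={kmx}->k={kmx - 1}")
    while dsum() < target_sum:
        # promote below the cutoff when possible, so a single node is never
        # pushed far beyond the power-law tail
        kmx = max(k for k, v in counts.items() if v > 0)
        below = [k for k, v in counts.items() if v > 0 and k < kmx]
        k_from = max(below) if below else kmx
        if k_from + 1 > N_tgt - 1:
            raise InfeasibleTargetsError("cannot raise degree sum within the k<=N-1 cap")
        counts[k_from] -= 1
        counts[k_from + 1] = counts.get(k_from + 1, 0) + 1
        adjustments.append(f"move one node k={k_from}->k={k_from + 1}")

    model.adjustments = adjustments
    model.n_adjustments = len(adjustments)
    if adjustments:
        log.debug(
            "SF sequence (N=%d, K=%d, b=%.3g): %d integer adjustments",
            N_tgt, K_tgt, b, len(adjustments),
        )
    seq = DegreeSequence(counts)
    assert seq.n_nodes == N_tgt and seq.degree_sum == target_sum
    return seq


def realize_degree_sequence(
    seq: DegreeSequence, seed, max_retries: int = MAX_RETRIES
) -> InteractionNetwork:
    """Wire a simple connected graph whose degree histogram equals ``seq``
    exactly.

    Stub-matching: nodes are processed in descending target degree and each
    remaining stub is paired with a uniformly random node that still has
    free stubs, is not the focal node and is not already a neighbour. A
    dead end (no admissible partner) or a disconnected result triggers a
    full restart, up to ``max_retries`` attempts.
    """
    if seq.degree_sum % 2 != 0:
        raise GenerationFailureError("degree sum is odd; sequence not graphical")
    degrees = seq.degree_list()
    n = degrees.shape[0]
    if n == 0:
        raise InvalidInputError("empty degree sequence")
    if degrees.max(initial=0) > n - 1:
        raise GenerationFailureError("a degree exceeds n-1; sequence not graphical")
    rng = np.random.default_rng(seed)
    for attempt in range(1, max_retries + 1):
        edges = _match_stubs(degrees, rng)
        if edges is None:
            continue
        net = InteractionNetwork(n, np.array(edges, dtype=np.int64))
        if is_connected(net):
            return net
    raise GenerationFailureError(
        f"degree-sequence realization failed in {max_retries} attempts",
        attempts=max_retries,
    )


def _match_stubs(degrees: np.ndarray, rng: np.random.Generator):
    """One stub-matching attempt; returns an edge list or None.

    Nodes are processed in descending target degree; each free stub is
    paired with a uniformly random node that still has free stubs and is
    not yet a neighbour. Sequences with a long minimum-degree tail almost
    always strand their last stubs among mutual neighbours, so a genuine
    dead end is resolved by the standard degree-preserving edge swap
    (remove a random edge (u, v), reconnect its endpoints to the stuck
    stubs) before giving up on the attempt.
    """
    n = degrees.shape[0]
    rem = degrees.copy()
    neighbors: list[set[int]] = [set() for _ in range(n)]
    edges: list[tuple[int, int]] = []
    n_swaps = 0
    for i in range(n):
        while rem[i] > 0:
            mask = rem > 0
            mask[i] = False
            if neighbors[i]:
                mask[list(neighbors[i])] = False
            cand = np.flatnonzero(mask)
            if cand.size:
                j = int(cand[rng.integers(cand.size)])
                neighbors[i].add(j)
                neighbors[j].add(i)
                edges.append((i, j))
                rem[i] -= 1
                rem[j] -= 1
                continue
            # dead end: pick the partner whose stub we must consume
            others = np.flatnonzero(rem > 0)
            others = others[others != i]
            if others.size:
                j = int(others[rng.integers(others.size)])
            elif rem[i] >= 2:
                j = i
            else:
                return None  # lone odd stub: not repairable
            if not _edge_swap_repair(i, j, rng, edges, neighbors):
                return None
            rem[i] -= 1
            rem[j] -= 1
            n_swaps += 1
    if n_swaps:
        log.debug("stub matching needed %d edge-swap repairs", n_swaps)
    return edges


def _edge_swap_repair(i, j, rng, edges, neighbors, tries: int = 500) -> bool:
    """Consume one free stub of ``i`` and of ``j`` (``i == j`` allowed) by
    splitting a random existing edge (u, v) into (i, u) and (j, v)."""
    for _ in range(tries):
        k = int(rng.integers(len(edges)))
        u, v = edges[k]
        if rng.random() < 0.5:
            u, v = v, u
        if (
            u == i or u == j or v == i or v == j
            or u in neighbors[i] or v in neighbors[j]
        ):
            continue
        del edges[k]
        neighbors[u].discard(v)
        neighbors[v].discard(u)
        edges.append((i, u))
        edges.append((j, v))
        neighbors[i].add(u)
        neighbors[u].add(i)
        neighbors[j].add(v)
        neighbors[v].add(j)
        return True
    return False


# ---------------------------------------------------------------------------
# Superposition protocol
# ---------------------------------------------------------------------------


def superpose(
    nn: InteractionNetwork,
    rnd: InteractionNetwork,
    p: float,
    seed,
    max_retries: int = MAX_RETRIES,
) -> InteractionNetwork:
    """Interpolate between the lattice network and a random network at
    constant edge count.

    Deletes ``round(p K)`` random links from the lattice network and the
    complementary number from the random network, then superimposes the
    survivors. Edges retained from both parents can coincide; the deficit
    is refilled with uniformly random absent edges so the result always has
    exactly ``K`` links. The result must be connected (bounded retries).
    ``p = 0`` returns the lattice edge set exactly; ``p = 1`` the random one.
    """
    if not 0.0 <= p <= 1.0:
        raise InvalidInputError(f"p must lie in [0, 1], got {p}")
    if nn.n_nodes != rnd.n_nodes:
        raise InvalidInputError("node counts differ between parent networks")
    if nn.n_edges != rnd.n_edges:
        raise InvalidInputError("edge counts differ between parent networks")
    K = nn.n_edges
    n = nn.n_nodes
    m = _round_half_away(p * K)  # links deleted from NN == links kept from rnd
    rng = np.random.default_rng(seed)
    for attempt in range(1, max_retries + 1):
        keep_nn = rng.choice(K, size=K - m, replace=False)
        keep_rnd = rng.choice(K, size=m, replace=False)
        chosen = {
            int(i) * n + int(j) for i, j in nn.edges[keep_nn]
        } | {int(i) * n + int(j) for i, j in rnd.edges[keep_rnd]}
        deficit = K - len(chosen)
        refills = 0
        while len(chosen) < K:
            i = int(rng.integers(n))
            j = int(rng.integers(n))
            if i == j:
                continue
            key = i * n + j if i < j else j * n + i
            if key in chosen:
                continue
            chosen.add(key)
            refills += 1
        if deficit:
            log.debug(
                "superpose(p=%.3g): %d overlapping links refilled at random",
                p, refills,
            )
        keys = np.fromiter(chosen, dtype=np.int64)
        net = InteractionNetwork(n, np.column_stack(np.divmod(keys, n)))
        if is_connected(net):
            return net
    raise GenerationFailureError(
        f"superposition failed to produce a connected graph in {max_retries} attempts",
        attempts=max_retries,
    )
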