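"""Noise sweeps over interpolated topologies.

A bifurcation sweep runs the chosen model over a grid of noise intensities
at one topology setting, drawing a fresh network realization for every run
(the superposition is random, so each run sees its own), starting from the
fully aligned state and recording per-run stationary polarization
statistics. Critical-noise curves repeat this over a grid of the
topological control parameter ``p``.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dynamics import AEParams, VNParams, assign_rest_lengths, init_aligned, run_model
from .exceptions import (
    InvalidInputError,
    InvalidSpecError,
    UnbracketedTransitionError,
)
from .network import (
    InteractionNetwork,
    LatticeSpec,
    SFDegreeModel,
    build_er,
    build_nn_lattice,
    realize_degree_sequence,
    solve_sf_degree_sequence,
    superpose,
)
from .observables import (
    CriticalNoiseEstimate,
    eta_c_branch_loss,
    eta_c_variance_peak,
)

ALIGNED_HEADING = np.pi / 2  # agents initially head "up", as in the lattice snapshots


@dataclass(frozen=True)
class TopologySpec:
    """One point in topology space: a lattice of side ``L`` whose edge set
    is interpolated toward an ER (``family="nn2er"``) or SF
    (``family="nn2sf"``, exponent ``b``) random network at parameter ``p``.
    ``family="nn"`` is shorthand for the pure lattice."""

    family: str
    L: int
    p: float = 0.0
    b: float = -2.0
    k_min: int = 2

    def __post_init__(self):
        if self.family not in ("nn", "nn2er", "nn2sf"):
            raise InvalidSpecError(f"unknown topology family {self.family!r}")
        if not 0.0 <= self.p <= 1.0:
            raise InvalidSpecError("p must lie in [0, 1]")
        if self.family == "nn2sf" and self.b >= 0:
            raise InvalidSpecError("b must be negative for the SF family")


@functools.lru_cache(maxsize=64)
def _sf_sequence(n_nodes: int, n_edges: int, b: float, k_min: int):
    model = SFDegreeModel(N_tgt=n_nodes, K_tgt=n_edges, b=b, k_min=k_min)
    return solve_sf_degree_sequence(model)


def make_network(spec: TopologySpec, seed) -> tuple[np.ndarray, InteractionNetwork]:
    """Build one network realization for a topology point.

    Returns ``(positions, network)``; positions are always the underlying
    lattice coordinates (they seed the AE rest lengths even for long-range
    links). ``p = 0`` gives the lattice exactly, ``p = 1`` a pure random
    network; in between the two edge sets are superposed at constant K.
    """
    lattice = LatticeSpec(spec.L)
    positions, nn = build_nn_lattice(lattice)
    if spec.family == "nn" or spec.p == 0.0:
        return positions, nn
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    s_rand, s_mix = ss.spawn(2)
    if spec.family == "nn2er":
        rnd = build_er(lattice.n_nodes, lattice.n_edges, s_rand)
    else:
        seq = _sf_sequence(lattice.n_nodes, lattice.n_edges, spec.b, spec.k_min)
        rnd = realize_degree_sequence(seq, s_rand)
    if spec.p == 1.0:
        return positions, rnd
    return positions, superpose(nn, rnd, spec.p, s_mix)


# ---------------------------------------------------------------------------
# Sweep container
# ---------------------------------------------------------------------------


@dataclass
class SweepResult:
    """Per-(p, eta, run) stationary polarization statistics.

    ``data`` columns: model, family, b, p, eta, run, seed, psi_mean,
    psi_var, n_samples — one row per run, where psi_mean / psi_var are the
    mean and population variance of the post-burn-in polarization samples.
    """

    data: pd.DataFrame
    meta: dict = field(default_factory=dict)

    COLUMNS = (
        "model", "family", "b", "p", "eta", "run",
        "seed", "psi_mean", "psi_var", "n_samples",
    )

    def eta_grid(self, p=None) -> np.ndarray:
        d = self.data if p is None else self.data[self.data.p == p]
        return np.sort(d.eta.unique())

    def mean_psi(self, p=None) -> tuple[np.ndarray, np.ndarray]:
        """Run-averaged stationary polarization per noise level."""
        d = self.data if p is None else self.data[self.data.p == p]
        g = d.groupby("eta").psi_mean.mean()
        return g.index.to_numpy(), g.to_numpy()

    def variance(self, p=None, how: str = "pooled") -> tuple[np.ndarray, np.ndarray]:
        """``Var(psi_eta)`` per noise level.

        ``how="pooled"`` pools every post-burn-in sample of every run at
        that noise level (within- plus between-run fluctuations);
        ``how="run_means"`` is the variance of the per-run means.
        """
        d = self.data if p is None else self.data[self.data.p == p]
        etas = np.sort(d.eta.unique())
        out = np.empty(etas.size)
        for k, eta in enumerate(etas):
            cell = d[d.eta == eta]
            if how == "run_means":
                out[k] = cell.psi_mean.to_numpy().var()
            elif how == "pooled":
                w = cell.n_samples.to_numpy().astype(float)
                w /= w.sum()
                m = float((w * cell.psi_mean).sum())
                second = float((w * (cell.psi_var + cell.psi_mean**2)).sum())
                out[k] = second - m * m
            else:
                raise InvalidInputError(f"unknown variance mode {how!r}")
        return etas, out

    def to_csv(self, path) -> None:
        path = Path(path)
        self.data.to_csv(path, index=False)
        sidecar = path.with_suffix(".meta.yaml")
        with open(sidecar, "w") as fh:
            yaml.safe_dump(self.meta, fh, sort_keys=True)

    @classmethod
    def from_csv(cls, path) -> "SweepResult":
        path = Path(path)
        data = pd.read_csv(path)
        sidecar = path.with_suffix(".meta.yaml")
        meta = {}
        if sidecar.exists():
            with open(sidecar) as fh:
                meta = yaml.safe_load(fh) or {}
        return cls(data, meta)


# ---------------------------------------------------------------------------
# Drivers
# ---------------------------------------------------------------------------


def bifurcation_sweep(
    model: str,
    topology: TopologySpec,
    eta_grid,
    runs: int,
    steps: int,
    seed,
    burn_in: float = 0.5,
    ae_params: AEParams | None = None,
) -> SweepResult:
    """Stationary polarization versus noise at one topology point.

    For every noise level, ``runs`` independent runs are performed, each on
    a freshly drawn network realization, each initialized fully aligned.
    """
    model = model.lower()
    if model not in ("vn", "ae"):
        raise InvalidSpecError(f"unknown model {model!r}")
    eta_grid = np.asarray(eta_grid, dtype=np.float64)
    if eta_grid.size == 0 or runs < 1 or steps < 1:
        raise InvalidSpecError("empty grid or non-positive runs/steps")
    root = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    rows = []
    for ei, eta in enumerate(eta_grid):
        for run in range(runs):
            # stable per-cell derivation: independent of grid iteration order
            cell_ss = np.random.SeedSequence(
                entropy=root.entropy, spawn_key=tuple(root.spawn_key) + (ei, run)
            )
            net_ss, dyn_ss = cell_ss.spawn(2)
            positions, network = make_network(topology, net_ss)
            state = init_aligned(positions, ALIGNED_HEADING)
            if model == "ae":
                network = assign_rest_lengths(network, positions)
                params = ae_params or AEParams(eta=float(eta))
                params = AEParams(
                    eta=float(eta), v0=params.v0, alpha=params.alpha,
                    beta=params.beta, kappa=params.kappa, dt=params.dt,
                )
            else:
                state.positions = None
                params = VNParams(eta=float(eta))
            psi, _ = run_model(
                model, network, params, steps,
                rng=np.random.default_rng(dyn_ss), initial_state=state,
            )
            start = int(np.floor(burn_in * psi.shape[0]))
            tail = psi[start:]
            rows.append(
                dict(
                    model=model, family=topology.family, b=topology.b,
                    p=topology.p, eta=float(eta), run=run,
                    seed=int(cell_ss.generate_state(1)[0] % (2**31)),
                    psi_mean=float(tail.mean()), psi_var=float(tail.var()),
                    n_samples=int(tail.size),
                )
            )
    data = pd.DataFrame(rows, columns=list(SweepResult.COLUMNS))
    meta = dict(
        model=model, family=topology.family, L=topology.L, b=topology.b,
        p=topology.p, runs=runs, steps=steps, burn_in=burn_in,
        seed=int(root.entropy) if root.entropy is not None else None,
        eta_grid=[float(e) for e in eta_grid],
    )
    return SweepResult(data, meta)


def estimate_eta_c(
    sweep: SweepResult,
    method: str,
    threshold: float = 0.5,
    var_how: str = "pooled",
    p=None,
) -> CriticalNoiseEstimate:
    """Apply one of the two critical-noise criteria to sweep data."""
    if method == "variance_peak":
        etas, var = sweep.variance(p=p, how=var_how)
        return eta_c_variance_peak(etas, var)
    if method == "branch_loss":
        etas, mean = sweep.mean_psi(p=p)
        return eta_c_branch_loss(etas, mean, threshold=threshold)
    raise InvalidSpecError(f"unknown eta_c method {method!r}")


def eta_c_vs_p_curve(
    model: str,
    family: str,
    L: int,
    p_grid,
    eta_grid,
    runs: int,
    steps: int,
    seed,
    b: float = -2.0,
    burn_in: float = 0.5,
    threshold: float = 0.5,
    var_how: str = "pooled",
    method: str | None = None,
    ae_params: AEParams | None = None,
) -> pd.DataFrame:
    """Critical noise as a function of the topological control parameter.

    The estimation criterion follows the transition type of each model:
    variance peak for VN (continuous transition), ordered-branch loss for
    AE (discontinuous). Returns a DataFrame (family, b, p, eta_c, method).
    """
    model = model.lower()
    if method is None:
        method = "variance_peak" if model == "vn" else "branch_loss"
    root = np.random.SeedSequence(seed)
    records = []
    for pi, p in enumerate(np.asarray(p_grid, dtype=np.float64)):
        spec = TopologySpec(family=family, L=L, p=float(p), b=b)
        sweep = bifurcation_sweep(
            model, spec, eta_grid, runs, steps,
            seed=np.random.SeedSequence(entropy=root.entropy, spawn_key=(1000 + pi,)),
            burn_in=burn_in, ae_params=ae_params,
        )
        est = estimate_eta_c(sweep, method, threshold=threshold, var_how=var_how)
        records.append(
            dict(family=family, b=b, p=float(p), eta_c=est.eta_c, method=est.method)
        )
    return pd.DataFrame.from_records(records)


def _mean_stationary_psi(
    model, topology, eta, runs, steps, root, burn_in, ae_params
) -> float:
    sweep = bifurcation_sweep(
        model, topology, [eta], runs, steps,
        seed=np.random.SeedSequence(
            entropy=root.entropy, spawn_key=(int(round(eta * 1e6)),)
        ),
        burn_in=burn_in, ae_params=ae_params,
    )
    return float(sweep.data.psi_mean.mean())


def adaptive_branch_loss(
    family: str,
    L: int,
    p: float,
    eta_lo: float,
    eta_hi: float,
    runs: int,
    steps: int,
    seed,
    b: float = -2.0,
    threshold: float = 0.5,
    burn_in: float = 0.5,
    refinements: int = 4,
    ae_params: AEParams | None = None,
    model: str = "ae",
) -> CriticalNoiseEstimate:
    """Branch-loss critical noise with bisection-refined brackets.

    Applies the same criterion as :func:`eta_c_branch_loss` — the midpoint
    between the highest tested noise with an ordered stationary solution and
    the next tested value — but chooses the tested noise values adaptively:
    starting from an ordered/disordered bracket, each refinement simulates
    the bracket midpoint (``runs`` fresh network realizations from the
    aligned state) and keeps the half interval containing the branch loss.
    Resolves ``eta_c`` to ``(eta_hi - eta_lo) / 2**refinements`` at a cost
    logarithmic in that resolution.
    """
    topology = TopologySpec(family=family, L=L, p=p, b=b)
    root = np.random.SeedSequence(seed)
    lo, hi = float(eta_lo), float(eta_hi)
    psi_lo = _mean_stationary_psi(model, topology, lo, runs, steps, root,
                                  burn_in, ae_params)
    if psi_lo < threshold:
        raise UnbracketedTransitionError(
            f"lower bound eta={lo} is already disordered (psi={psi_lo:.3f})"
        )
    psi_hi = _mean_stationary_psi(model, topology, hi, runs, steps, root,
                                  burn_in, ae_params)
    if psi_hi >= threshold:
        raise UnbracketedTransitionError(
            f"upper bound eta={hi} is still ordered (psi={psi_hi:.3f})"
        )
    for _ in range(refinements):
        mid = 0.5 * (lo + hi)
        psi_mid = _mean_stationary_psi(model, topology, mid, runs, steps, root,
                                       burn_in, ae_params)
        if psi_mid >= threshold:
            lo = mid
        else:
            hi = mid
    return CriticalNoiseEstimate(0.5 * (lo + hi), "branch_loss", (lo, hi))


def eta_c_vs_b_curve(
    L: int,
    b_grid,
    eta_grid,
    runs: int,
    steps: int,
    seed,
    burn_in: float = 0.5,
    threshold: float = 0.5,
    ae_params: AEParams | None = None,
) -> pd.DataFrame:
    """AE critical noise versus the scale-free exponent at ``p = 1``.

    Each ``b`` gets its own fully random SF topology (same N, K as the
    lattice); steeper exponents pile more agents at the minimum degree.
    Returns a DataFrame (b, eta_c, method).
    """
    root = np.random.SeedSequence(seed)
    records = []
    for bi, b in enumerate(np.asarray(b_grid, dtype=np.float64)):
        spec = TopologySpec(family="nn2sf", L=L, p=1.0, b=float(b))
        sweep = bifurcation_sweep(
            "ae", spec, eta_grid, runs, steps,
            seed=np.random.SeedSequence(entropy=root.entropy, spawn_key=(2000 + bi,)),
            burn_in=burn_in, ae_params=ae_params,
        )
        est = estimate_eta_c(sweep, "branch_loss", threshold=threshold)
        records.append(dict(b=float(b), eta_c=est.eta_c, method=est.method))
    return pd.DataFrame.from_records(records)
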