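"""Order parameter and critical-noise estimators.

The degree of alignment is measured by the polarization
``psi = |sum_i n_i| / N``, the norm of the mean heading unit vector:
1 for perfect alignment, ~N**-1/2 for fully disordered headings.

Two estimators locate the critical noise ``eta_c`` of the order-disorder
transition from sweep data:

* ``variance_peak`` (continuous transitions, used for VN): the abscissa of
  the vertex of a parabola through the maximum-variance grid point of
  ``Var(psi_eta)`` and its two neighbours;
* ``branch_loss`` (discontinuous transitions, used for AE): the midpoint
  between the highest noise level at which an ordered stationary solution
  was found and the next tested level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import SwarmState
from .exceptions import (
    BoundaryPeakError,
    FlatVarianceError,
    InsufficientDataError,
    InvalidInputError,
    UnbracketedTransitionError,
)


def polarization(state) -> float:
    """Polarization in [0, 1] of a state or an array of headings."""
    headings = state.headings if isinstance(state, SwarmState) else np.asarray(state)
    if headings.size == 0:
        raise InvalidInputError("polarization needs at least one agent")
    return float(
        np.hypot(np.cos(headings).mean(), np.sin(headings).mean())
    )


def stationary_mean(psi_series, burn_in_fraction: float = 0.5) -> float:
    """Mean of a polarization series after discarding the initial transient.

    ``burn_in_fraction`` of the samples (rounded down) is dropped from the
    front; at least one sample must remain.
    """
    psi_series = np.asarray(psi_series, dtype=np.float64)
    if not 0.0 <= burn_in_fraction < 1.0:
        raise InvalidInputError("burn_in_fraction must lie in [0, 1)")
    start = int(np.floor(burn_in_fraction * psi_series.shape[0]))
    if psi_series.shape[0] == 0 or start >= psi_series.shape[0]:
        raise InsufficientDataError("series shorter than the burn-in window")
    return float(psi_series[start:].mean())


@dataclass(frozen=True)
class CriticalNoiseEstimate:
    """A critical-noise value with the evidence that produced it.

    ``diagnostics`` holds the three ``(eta, Var)`` points (variance_peak)
    or the bracketing ``(eta_ordered, eta_disordered)`` pair (branch_loss).
    """

    eta_c: float
    method: str
    diagnostics: tuple = field(default=())


def eta_c_variance_peak(etas, variances) -> CriticalNoiseEstimate:
    """Critical noise from the peak of ``Var(psi_eta)`` over the noise grid.

    Fits the unique quadratic through the maximum-variance point and its two
    grid neighbours and returns the vertex abscissa. The maximum must be
    unique and interior to the grid.
    """
    etas = np.asarray(etas, dtype=np.float64)
    variances = np.asarray(variances, dtype=np.float64)
    if etas.shape != variances.shape or etas.ndim != 1:
        raise InvalidInputError("etas and variances must be matching 1-D arrays")
    if etas.size < 3:
        raise InsufficientDataError("need at least three (eta, Var) points")
    if np.any(np.diff(etas) <= 0):
        raise InvalidInputError("eta grid must be strictly increasing")
    vmax = variances.max()
    peaks = np.flatnonzero(variances == vmax)
    if peaks.size != 1:
        raise FlatVarianceError("variance profile has no unique maximum")
    k = int(peaks[0])
    if k == 0 or k == etas.size - 1:
        raise BoundaryPeakError(
            f"variance maximum at grid edge eta={etas[k]:.4g}; widen the grid"
        )
    x0, x1, x2 = etas[k - 1 : k + 2]
    y0, y1, y2 = variances[k - 1 : k + 2]
    # vertex of the Lagrange parabola through the three points
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    b = (x2 * x2 * (y0 - y1) + x1 * x1 * (y2 - y0) + x0 * x0 * (y1 - y2)) / denom
    if a >= 0:
        raise FlatVarianceError("parabola through the peak is not concave")
    eta_c = -b / (2.0 * a)
    return CriticalNoiseEstimate(
        float(eta_c),
        "variance_peak",
        ((float(x0), float(y0)), (float(x1), float(y1)), (float(x2), float(y2))),
    )


def eta_c_branch_loss(
    etas, mean_psi, threshold: float = 0.5
) -> CriticalNoiseEstimate:
    """Critical noise as the midpoint between the highest noise level whose
    stationary polarization still marks an ordered state (mean psi >=
    ``threshold``) and the next tested level."""
    etas = np.asarray(etas, dtype=np.float64)
    mean_psi = np.asarray(mean_psi, dtype=np.float64)
    if etas.shape != mean_psi.shape or etas.ndim != 1:
        raise InvalidInputError("etas and mean_psi must be matching 1-D arrays")
    if np.any(np.diff(etas) <= 0):
        raise InvalidInputError("eta grid must be strictly increasing")
    ordered = mean_psi >= threshold
    if not ordered.any():
        raise UnbracketedTransitionError(
            "no ordered cell on the grid (first point already disordered)"
        )
    last = int(np.flatnonzero(ordered)[-1])
    if last == etas.size - 1:
        raise UnbracketedTransitionError(
            "ordered branch persists to the end of the grid; extend it"
        )
    eta_lo, eta_hi = float(etas[last]), float(etas[last + 1])
    return CriticalNoiseEstimate(
        0.5 * (eta_lo + eta_hi), "branch_loss", (eta_lo, eta_hi)
    )
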