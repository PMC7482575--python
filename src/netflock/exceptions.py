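"""Exception hierarchy for netflock."""


class NetflockError(Exception):
    """Base class for all netflock-specific errors."""


class InvalidSpecError(NetflockError, ValueError):
    """A generator or model specification violates its preconditions."""


class InvalidInputError(NetflockError, ValueError):
    """Inputs to an operation are inconsistent (e.g. mismatched sizes)."""


class GenerationFailureError(NetflockError, RuntimeError):
    """A stochastic network generator exhausted its retry budget.

    Carries the number of attempts made so failures are diagnosable
    instead of silent.
    """

    def __init__(self, message: str, attempts: int | None = None):
        super().__init__(message)
        self.attempts = attempts


class InfeasibleTargetsError(NetflockError, ValueError):
    """Requested (N, K) targets cannot be met by any degree sequence."""


class DegenerateGeometryError(NetflockError, ValueError):
    """Two linked agents coincide, so a spring direction is undefined."""


class NumericalBlowupError(NetflockError, FloatingPointError):
    """A non-finite position or heading appeared during integration."""

    def __init__(self, message: str, step: int | None = None):
        super().__init__(message)
        self.step = step


class InsufficientDataError(NetflockError, ValueError):
    """A time series is too short for the requested statistic."""


class BoundaryPeakError(NetflockError, RuntimeError):
    """The variance maximum sits at the edge of the noise grid; the grid
    must be widened before the peak can be interpolated."""


class FlatVarianceError(NetflockError, RuntimeError):
    """No unique variance maximum exists (flat or tied profile)."""


class UnbracketedTransitionError(NetflockError, RuntimeError):
    """All sweep cells are ordered (or all disordered), so no transition
    point is bracketed by the noise grid."""
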