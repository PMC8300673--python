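"""Exception and warning types shared across the package."""


class JacrecError(Exception):
    """Base class for all package-specific errors."""


class DimensionError(JacrecError, ValueError):
    """Array shapes are inconsistent with the requested operation."""


class ValidationError(JacrecError, ValueError):
    """An input violates a documented invariant (asymmetry, bad pattern, ...)."""


class DegenerateSystemError(JacrecError, ValueError):
    """The least-squares system carries no information (e.g. all-zero design)."""


class UnstableSystemError(JacrecError, ValueError):
    """A stationary covariance was requested for a non-Hurwitz Jacobian."""


class NonConvergenceError(JacrecError, RuntimeError):
    """An iterative solver (steady-state search) failed to converge."""


class SimulationError(JacrecError, RuntimeError):
    """A stochastic integration produced unusable output (non-finite states)."""


class UnderdeterminedWarning(UserWarning):
    """Fewer structural constraints than needed for a determined reconstruction."""


class AsymmetryWarning(UserWarning):
    """A covariance input was asymmetric beyond round-off and was symmetrized."""


class RestartWarning(UserWarning):
    """A stochastic simulation was re-seeded after leaving the admissible region."""
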