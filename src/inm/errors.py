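"""Exception types shared across the package."""


class InmError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(InmError, ValueError):
    """A parameter or configuration value violates its domain constraints."""


class DimensionError(ValidationError):
    """Array/length mismatch between coupled objects."""


class GeometryError(ValidationError):
    """Inconsistent myelin/axon geometry (e.g. inner radius >= outer radius)."""


class IntegrationError(InmError, RuntimeError):
    """Time integration became unstable or left the physically plausible range."""


class SolverError(InmError, RuntimeError):
    """A numerical solver failed (stability violation, non-convergence)."""


class FitError(InmError, RuntimeError):
    """Curve fitting did not converge; carries the best residual found."""

    def __init__(self, message: str, best_rss: float | None = None):
        super().__init__(message)
        self.best_rss = best_rss
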