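"""Exception hierarchy for pnpbik."""


class PnpbikError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(PnpbikError, ValueError):
    """Invalid user input (non-electroneutral composition, bad config, ...)."""


class InfeasibleCompositionError(ValidationError):
    """Bulk composition over-packed: void fraction would be <= 0."""


class SaturationError(PnpbikError, ValueError):
    """A concentration state violates the hard packing bound (Gamma <= 0)."""


class ComplexRootError(PnpbikError, ValueError):
    """Spectral roots of the fourth-order operator left the real regime."""


class DegenerateGeometryError(PnpbikError, ZeroDivisionError):
    """A geometric denominator vanished (e.g. in the correlation factor)."""


class NoSolutionError(PnpbikError, RuntimeError):
    """A bracketed root solve found no sign change."""


class ConvergenceError(PnpbikError, RuntimeError):
    """Nonlinear iteration failed to reach tolerance."""

    def __init__(self, message: str, residual_history=None):
        super().__init__(message)
        self.residual_history = list(residual_history or [])


class ParseError(PnpbikError, ValueError):
    """Malformed input file."""
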