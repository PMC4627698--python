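"""Exception hierarchy for bcrsignal."""


class BcrSignalError(Exception):
    """Base class for all package errors."""


class ConfigurationError(BcrSignalError):
    """A required symbol, key or file is missing or malformed."""


class ValidationError(BcrSignalError):
    """A value violates a domain constraint (e.g. a nonpositive rate)."""


class DomainError(BcrSignalError):
    """An input lies outside the mathematical domain of an operation."""


class IntegrityError(BcrSignalError):
    """A conservation law is violated beyond tolerance."""


class NonConvergenceError(BcrSignalError):
    """Steady state was not reached within the allotted horizon."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class NormalizationError(BcrSignalError):
    """A normalization denominator is zero or undefined."""


class SimulationHalted(BcrSignalError):
    """A simulation exceeded its wall-time budget."""


class StiffnessError(BcrSignalError):
    """Too many integration failures during a sensitivity run."""


class DependencyError(BcrSignalError):
    """A workflow stage was requested before its inputs exist."""


class SurfaceError(BcrSignalError):
    """A response surface could not be evaluated (e.g. all points halted)."""
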