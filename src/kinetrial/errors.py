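"""Exception hierarchy shared across the package."""


class KinetrialError(Exception):
    """Base class for all package-specific errors."""


class TableauStructureError(KinetrialError):
    """A Butcher tableau is structurally malformed (wrong shapes/lengths)."""


class IntegrationError(KinetrialError):
    """A Runge-Kutta stage produced a non-finite derivative.

    Carries the time and stage index at which integration failed.
    """

    def __init__(self, message: str, t: float | None = None, stage: int | None = None):
        super().__init__(message)
        self.t = t
        self.stage = stage


class NonConvergenceError(KinetrialError):
    """Adaptive integration could not reach t_end within the step budget."""

    def __init__(self, message: str, t_reached: float | None = None):
        super().__init__(message)
        self.t_reached = t_reached


class DomainError(KinetrialError):
    """An input lies outside the mathematical domain of an operation."""


class UndefinedStatisticError(KinetrialError):
    """A statistic is undefined for the given data (e.g. zero variance)."""


class InsufficientDataError(KinetrialError):
    """Too few observations remain to carry out the requested analysis."""


class ConfigError(KinetrialError):
    """A configuration file or object violates the expected schema."""
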