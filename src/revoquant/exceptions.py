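"""Exception hierarchy for revoquant."""


class RevoquantError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(RevoquantError, ValueError):
    """A configuration object violates its invariants."""


class NoVarianceError(RevoquantError, ValueError):
    """An operation requires variance that the data do not have."""


class SpecError(RevoquantError, ValueError):
    """A model specification violates its flag dependencies."""


class FilteringError(RevoquantError, RuntimeError):
    """Particle filtering failed (e.g. all weights underflowed)."""

    def __init__(self, message, country=None, step=None):
        super().__init__(message)
        self.country = country
        self.step = step


class UnmappedCountryError(RevoquantError, KeyError):
    """A country is missing from a required mapping (no silent default)."""


class ConvergenceError(RevoquantError, RuntimeError):
    """No optimizer start converged; carries the trace of attempts."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace or []
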