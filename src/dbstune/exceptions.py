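"""Exception hierarchy shared across the package."""


class DBSTuneError(Exception):
    """Base class for all dbstune errors."""


class InvalidParameterError(DBSTuneError, ValueError):
    """A parameter is outside its valid range (e.g. filter cutoff at/above Nyquist)."""


class InsufficientDataError(DBSTuneError, ValueError):
    """The input carries too little data for the requested computation."""


class DegenerateDesignError(DBSTuneError, ValueError):
    """Observations do not identify the model (e.g. all at one frequency)."""


class NumericalError(DBSTuneError, RuntimeError):
    """A linear-algebra step failed even after jitter escalation."""


class ConvergenceError(DBSTuneError, RuntimeError):
    """An iterative optimizer failed to converge from every restart."""

    def __init__(self, message, best_objective=None):
        super().__init__(message)
        self.best_objective = best_objective


class NoFeasibleFrequencyError(DBSTuneError, ValueError):
    """The candidate grid is empty after applying the tolerability ceiling."""


class IntolerableFrequencyError(DBSTuneError, RuntimeError):
    """Raised by a patient when a stimulation frequency exceeds their ceiling.

    This is an *event*, not a bug: the session loop catches it, lowers the
    ceiling, and re-selects. The offending frequency is carried in
    ``frequency_hz``.
    """

    def __init__(self, frequency_hz):
        super().__init__(f"frequency {frequency_hz} Hz not tolerated")
        self.frequency_hz = frequency_hz


class ConfigValidationError(DBSTuneError, ValueError):
    """A configuration file violates the schema; ``fields`` lists offenders."""

    def __init__(self, message, fields=()):
        super().__init__(message)
        self.fields = list(fields)


class UnsupportedVersionError(DBSTuneError, ValueError):
    """A serialized file declares a format version this build cannot read."""
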