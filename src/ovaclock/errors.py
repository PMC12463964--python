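"""Exception hierarchy for ovaclock.

All package-specific failures derive from :class:`OvaclockError` so callers
(and the CLI) can catch one base class.
"""


class OvaclockError(Exception):
    """Base class for all ovaclock errors."""


class InvalidRecordError(OvaclockError):
    """A cohort record is missing or has out-of-domain predictor values."""


class SchemaError(OvaclockError):
    """A cohort file does not match the expected column schema."""


class DegenerateFitError(OvaclockError):
    """Model fitting is impossible: single-class outcome."""


class DegenerateDesignError(OvaclockError):
    """The design matrix is rank deficient (e.g. a zero-variance column)."""


class UndefinedMetricError(OvaclockError):
    """A metric (AUC, NRI) is undefined, e.g. only one outcome class present."""


class InsufficientDataError(OvaclockError):
    """Not enough data rows survive filtering to perform the operation."""


class CurveFitError(OvaclockError):
    """Nonlinear curve fitting failed to converge; carries the last iterate."""

    def __init__(self, message: str, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


class OutOfRangeError(OvaclockError):
    """A probability or score argument lies outside its valid domain."""


class ConfigError(OvaclockError):
    """Invalid configuration values."""
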