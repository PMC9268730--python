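"""Exception hierarchy for odorcal.

All package errors derive from :class:`OdorcalError` so callers can catch
everything with one clause; most also derive from the closest built-in
(``ValueError`` for bad values, etc.) so untargeted code still behaves sanely.
"""


class OdorcalError(Exception):
    """Base class for all odorcal errors."""


class InvalidReadingError(OdorcalError, ValueError):
    """An olfactometer dial reading is negative or non-finite."""


class InvalidEstimateError(OdorcalError, ValueError):
    """An individual threshold estimate is below 1 or non-finite."""


class EmptyPanelError(OdorcalError, ValueError):
    """A session has no individual threshold estimates."""


class InsufficientPanelError(OdorcalError, ValueError):
    """A session has fewer assessors than the required panel minimum."""


class BaselineError(OdorcalError, ValueError):
    """A baseline estimate is non-positive (corrupt clean-air segment)."""


class EmptyWindowError(OdorcalError, ValueError):
    """A sensor exposure window contains no samples."""


class AlignmentError(OdorcalError, ValueError):
    """Feature records and concentration records cannot be aligned."""


class DomainError(OdorcalError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class UnderdeterminedError(OdorcalError, ValueError):
    """Too few training rows for the number of explanatory variables."""


class SingularDesignError(OdorcalError, ValueError):
    """The regression design matrix is rank deficient."""


class DegenerateColumnError(OdorcalError, ValueError):
    """A zero-variance column cannot be scaled to unit variance."""


class UnsupportedModeError(OdorcalError, ValueError):
    """A model family does not support the requested feature mode."""


class LogDomainError(OdorcalError, ValueError):
    """Non-positive response values cannot be log-transformed for fitting."""


class GeometricMeanDomainError(OdorcalError, ValueError):
    """A geometric mean over non-positive values is undefined."""


class IncompatibleInputError(OdorcalError, ValueError):
    """New data does not match a fitted model's mode or channel roster."""


class InvalidInputError(OdorcalError, ValueError):
    """Generic invalid input to an evaluation operation."""


class InvalidSplitError(OdorcalError, ValueError):
    """A dataset lacks the train/test rows an operation requires."""


class NonInvertibleError(OdorcalError, ValueError):
    """A psychophysical fit with zero slope cannot be inverted."""


class ConfigError(OdorcalError, ValueError):
    """Invalid generator or pipeline configuration."""


class ParseError(OdorcalError, ValueError):
    """A delimited-text document violates its schema."""
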