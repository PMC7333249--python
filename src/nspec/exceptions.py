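"""Exception hierarchy.

Everything derives from :class:`NspecError` (itself a ``ValueError``) so
callers can catch package errors with a single ``except`` clause while
library code raises the most specific class available.
"""


class NspecError(ValueError):
    """Base class for all package errors."""


class ConfigurationError(NspecError):
    """An invalid configuration value (infeasible truncation, bad kind, ...)."""


class SizeError(NspecError):
    """A size/shape precondition on sample or band counts is violated."""


class ShapeError(SizeError):
    """Prediction-time column count does not match the training band count."""


class GridError(NspecError):
    """The wavelength grid violates a precondition (e.g. unequal spacing)."""


class RangeError(NspecError):
    """A requested wavelength range falls outside the available grid."""


class DomainError(NspecError):
    """Values outside the domain an operation is defined on (e.g. R <= 0 for CR)."""


class DegenerateDataError(NspecError):
    """A degenerate input (constant response, zero explained variance)."""
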