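"""Exception hierarchy shared across the package.

Everything derives from :class:`SdindexError` so callers can catch one base;
most errors also subclass ``ValueError`` to behave sanely in generic code.
"""


class SdindexError(Exception):
    """Base class for all sdindex errors."""


class InvalidParameterError(SdindexError, ValueError):
    """A function argument is outside its documented domain."""


class InvalidInputError(SdindexError, ValueError):
    """Input data violates a physical or structural constraint."""


class AlignmentError(SdindexError, ValueError):
    """Two series that must share a calendar do not."""


class CalendarError(SdindexError, ValueError):
    """Dates are not a contiguous daily Gregorian sequence."""


class SchemaError(SdindexError, ValueError):
    """A CSV file does not match the expected column layout."""


class DegenerateSampleError(SdindexError, ValueError):
    """A sample has no usable spread (all values identical, or all zero)."""


class InsufficientClimatologyError(SdindexError, ValueError):
    """Fewer contributing years than the configured minimum (default 30)."""


class UndefinedNormalizationError(SdindexError, ValueError):
    """A normalization denominator (e.g. sd of the observations) is zero."""
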