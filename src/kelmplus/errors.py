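"""Exception hierarchy.

All package errors derive from :class:`KelmPlusError` so callers can catch
broadly; the concrete classes also subclass ``ValueError`` to behave sanely
in generic numeric code.
"""


class KelmPlusError(Exception):
    """Base class for all errors raised by kelmplus."""


class InvalidInputError(KelmPlusError, ValueError):
    """An argument violates a precondition (non-finite pressure, C <= 0, ...)."""


class FormatError(KelmPlusError, ValueError):
    """A file does not conform to the expected tabular layout."""


class DegenerateInputError(KelmPlusError, ValueError):
    """Input is structurally valid but numerically degenerate
    (zero variance, all-zero kernel matrix, ...)."""


class AlignmentError(KelmPlusError, ValueError):
    """Subject rows of jointly used tables do not line up."""
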