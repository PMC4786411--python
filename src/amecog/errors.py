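"""Exception hierarchy shared across the pipeline."""


class AmecogError(Exception):
    """Base class for all package-specific errors."""


class FormatError(AmecogError):
    """A file does not conform to the expected container layout."""


class ValidationError(AmecogError, ValueError):
    """An in-memory object violates a documented invariant."""


class ParameterError(AmecogError, ValueError):
    """An argument is outside its documented domain."""


class InsufficientDataError(AmecogError):
    """Too few samples/channels/trials for the requested statistic."""


class WindowingError(AmecogError):
    """A requested analysis window cannot be placed on the data."""


class ReferenceError_(AmecogError):
    """A common-average-reference bank has no usable channels."""


class DegenerateInputError(AmecogError):
    """Zero-variance or otherwise degenerate input to a statistic."""
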