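"""Exception hierarchy shared across the package."""


class AVTBWError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(AVTBWError, ValueError):
    """A parameter is outside its documented domain."""


class InvalidDesignError(AVTBWError, ValueError):
    """A trial design is internally inconsistent (duplicate SOAs,
    non-integer implied pulse count, ...)."""


class DegenerateInputError(AVTBWError, ValueError):
    """Input carries no usable signal (e.g. an all-zero waveform)."""


class InvalidDataError(AVTBWError, ValueError):
    """A response table violates the schema; the message names the
    offending row/value."""


class InsufficientDataError(AVTBWError, ValueError):
    """Too few defined points to fit the requested model."""
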