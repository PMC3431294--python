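"""Exception hierarchy shared across the package.

All errors derive from :class:`ATDError` so callers (and the CLI) can
distinguish package failures from programming errors.
"""


class ATDError(Exception):
    """Base class for all package errors."""


class InvalidInputError(ATDError, ValueError):
    """The data handed to an operation violates its preconditions."""


class InvalidParameterError(ATDError, ValueError):
    """A parameter value is outside its allowed domain."""


class UnsupportedFormatError(ATDError, ValueError):
    """An input file is in a format the package does not read."""
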