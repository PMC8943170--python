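"""Exception hierarchy.

Everything raised deliberately by this package derives from
:class:`EdkernelError`, so callers can catch one base class.  Parameter and
configuration errors additionally derive from :class:`ValueError` to behave
well with generic call sites.
"""


class EdkernelError(Exception):
    """Base class for all errors raised by edkernel."""


class ParameterError(EdkernelError, ValueError):
    """An argument value is outside its documented domain."""


class ConfigurationError(EdkernelError, ValueError):
    """A dialect / config object references something that does not exist."""


class RecordError(EdkernelError):
    """A single input record is malformed; carries the offending row number."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message if row is None else f"row {row}: {message}")
        self.row = row


class FormatError(EdkernelError):
    """A serialized matrix or table violates its on-disk format contract."""
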