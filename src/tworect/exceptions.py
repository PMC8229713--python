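"""Exception hierarchy.

Errors are split by who can fix them: :class:`ConfigurationError` for bad
parameters or sample selections, :class:`FormatError` for malformed input
files, :class:`DomainError` for mathematically invalid arguments, and
:class:`EstimationError` for data on which a fit cannot be carried out.
"""


class TworectError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TworectError):
    """A parameter, option, or sample selection is invalid."""


class FormatError(TworectError):
    """An input file violates its declared format."""


class DomainError(TworectError):
    """A numeric argument lies outside its mathematical domain."""


class EstimationError(TworectError):
    """A statistical fit cannot be performed on the given data."""
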