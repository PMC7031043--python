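"""Exception hierarchy shared across the package.

All errors raised on bad user input derive from :class:`MediatorNetError`,
so callers (and the CLI) can map them to a validation exit code.
"""


class MediatorNetError(Exception):
    """Base class for all package errors."""


class FormatError(MediatorNetError):
    """Malformed input file (bad column count, unparseable field, ...)."""


class ParameterError(MediatorNetError):
    """Out-of-range or inconsistent parameter value."""


class ValidationError(MediatorNetError):
    """Data that parses but violates a domain invariant."""


class SizeError(MediatorNetError):
    """A combinatorial guard was exceeded (oracle routines only)."""
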