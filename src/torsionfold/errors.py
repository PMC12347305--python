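"""Exception hierarchy.

All errors raised by the package derive from :class:`TorsionfoldError` so
callers can catch everything with one clause; the subclasses distinguish
bad file contents, bad parameter tables, bad argument values and numeric
degeneracies.
"""


class TorsionfoldError(Exception):
    """Base class for all package errors."""


class FormatError(TorsionfoldError, ValueError):
    """A file does not conform to its documented on-disk format."""


class ConfigurationError(TorsionfoldError, ValueError):
    """A parameter table or run configuration is incomplete or inconsistent."""


class DomainError(TorsionfoldError, ValueError):
    """An argument lies outside the operation's domain."""


class NumericError(TorsionfoldError, ArithmeticError):
    """A numeric degeneracy (non-finite input, coincident atoms, ...)."""
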