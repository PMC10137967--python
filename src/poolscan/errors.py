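"""Exception hierarchy.

``ValidationError`` covers bad user input (parameters, names, ranges) and maps
to CLI exit code 1; every other :class:`PoolscanError` maps to exit code 2.
"""


class PoolscanError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(PoolscanError):
    """Invalid parameter, name, or value supplied by the caller."""


class FormatError(PoolscanError):
    """A file could not be parsed in the declared format."""


class UndefinedResultError(PoolscanError):
    """The requested statistic is undefined for the given input
    (e.g. no usable sites, or an empty empirical distribution)."""
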