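"""Exception hierarchy.

All package errors derive from :class:`PhenonetError` so callers can catch
one base class; the subclasses separate bad configuration, unparseable
input, and data that violates a method's preconditions.
"""


class PhenonetError(Exception):
    """Base class for all errors raised by phenonet."""


class ConfigurationError(PhenonetError):
    """A configuration (column mapping, generator config, run config) is invalid."""


class ParseError(PhenonetError):
    """An input file could not be parsed; the message names the offending row."""


class DataError(PhenonetError, ValueError):
    """Input data violates a precondition (empty input, unknown species, ...)."""
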