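"""Exception hierarchy.

Everything raised deliberately by this package derives from
:class:`MethentropyError`, so callers (and the CLI) can distinguish
validation problems (bad inputs, exit code 2) from runtime failures
(exit code 3).
"""


class MethentropyError(Exception):
    """Base class for all errors raised by methentropy."""


class ParseError(MethentropyError):
    """A file could not be parsed; the message names the file and line."""


class ValidationError(MethentropyError):
    """An in-memory object or argument violates a documented invariant."""


class ConfigurationError(MethentropyError):
    """A configuration value is missing, unknown, or out of its domain."""


class UsageError(MethentropyError):
    """An operation was applied to an object it is not defined for."""


class InsufficientDataError(MethentropyError):
    """Too few observations to compute the requested statistic."""


class EmptyDistributionError(MethentropyError):
    """No qualifying reads at a locus; distinct from an all-zero count vector."""


class UndefinedStatisticError(MethentropyError):
    """The statistic is mathematically undefined on this input (e.g. zero variance)."""
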