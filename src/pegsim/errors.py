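"""Exception hierarchy for pegsim.

All errors raised by the library derive from :class:`PegsimError` so callers
can catch everything with one clause; CLI maps them to exit codes.
"""


class PegsimError(Exception):
    """Base class for all pegsim errors."""


class ParameterError(PegsimError, ValueError):
    """An argument is outside its documented domain."""


class DataError(PegsimError, ValueError):
    """Input data violate an assumption (e.g. nonpositive baseline)."""


class FormatError(PegsimError, ValueError):
    """A file does not conform to the documented CSV dialect."""


class ConfigError(PegsimError, ValueError):
    """Configuration file is malformed or contains unknown keys."""


class IncompatibleTracesError(PegsimError, ValueError):
    """Two traces cannot be combined (different grids or kinds)."""


class MissingChannelError(PegsimError, KeyError):
    """A recording has no channel with the requested functionalization."""


class NoDeclineError(PegsimError, ValueError):
    """A trace has no declining section after its peak."""


class DegenerateIntervalError(PegsimError, ValueError):
    """The requested slope interval is empty or undefined."""


class DegenerateFitError(PegsimError, ValueError):
    """A regression problem has no unique solution."""


class InsufficientBlanksError(PegsimError, ValueError):
    """Too few blank replicates for a limit-of-detection estimate."""
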