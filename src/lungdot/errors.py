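"""Exception hierarchy for lungdot."""


class LungdotError(Exception):
    """Base class for all lungdot errors."""


class InvalidParameterError(LungdotError, ValueError):
    """A parameter is outside its documented domain."""


class ConfigurationError(LungdotError, ValueError):
    """A configuration file or option set is malformed."""


class FormatError(LungdotError, OSError):
    """An input file could not be read or has an unsupported format."""


class InsufficientSupportError(LungdotError, ValueError):
    """Not enough data points to carry out a fit."""


class VerticalLineError(LungdotError, ArithmeticError):
    """A fitted line is vertical; its slope/intercept are undefined."""


class NoSkeletonError(LungdotError, ValueError):
    """A distance computation was requested against an empty skeleton."""
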