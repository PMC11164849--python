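"""Exception hierarchy shared across the package."""


class BorgAnchorError(Exception):
    """Base class for all package errors."""


class ConfigError(BorgAnchorError, ValueError):
    """Invalid configuration; the message names the offending field."""


class SchemaError(BorgAnchorError, ValueError):
    """A cohort file does not match the documented schema."""


class DomainError(BorgAnchorError, ValueError):
    """An argument lies outside the mathematically valid domain."""


class OutOfRangeError(DomainError):
    """A spline query lies outside the knot range (no extrapolation)."""


class ThresholdUndetectable(BorgAnchorError):
    """A record carries no usable lactate signal at all."""


class FitFailedError(BorgAnchorError):
    """A downstream consumer asked for results of a failed model fit."""
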