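"""Exception hierarchy used across the package.

All exceptions derive from :class:`ValueError` so that callers who do not
care about the distinction can catch a single base class.
"""


class NeurorefError(ValueError):
    """Base class for all package-specific errors."""


class ConfigurationError(NeurorefError):
    """An unknown name, missing designation or otherwise invalid configuration."""


class ValidationError(NeurorefError):
    """Input data violates a documented invariant."""


class ParseError(NeurorefError):
    """A file could not be parsed; the message names the offending line."""


class NumericalError(NeurorefError):
    """A numerical procedure failed (degenerate geometry, rank deficiency...)."""


class UndefinedMetricError(NeurorefError):
    """A metric is undefined for the given input (e.g. all-zero truth map)."""
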