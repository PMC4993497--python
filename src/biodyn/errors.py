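"""Exceptions shared across the package."""


class BiodynError(ValueError):
    """Base class for domain validation errors."""


class DegenerateLossError(BiodynError):
    """Total loss rate in a compartment denominator is not strictly positive."""


class InsufficientDataError(BiodynError):
    """Too few usable records or observations for the requested estimate."""


class UndefinedMetricError(BiodynError):
    """A statistic is undefined for the given input (e.g. zero-variance r2)."""
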