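"""Exception types shared across the pipeline stages."""


class DrlTimingError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(DrlTimingError, ValueError):
    """Malformed input data (non-monotone timestamps, negative times, ...)."""


class InvalidParameterError(DrlTimingError, ValueError):
    """A parameter vector violates its domain constraints."""


class InsufficientDataError(DrlTimingError, ValueError):
    """Too few observations for the requested computation."""


class DegenerateDataError(DrlTimingError, ValueError):
    """Data carry no information for fitting (e.g. all IRTs identical)."""


class EmptyDistributionError(DrlTimingError, ValueError):
    """A distribution was requested from an empty sample."""


class UndefinedEfficiencyError(DrlTimingError, ValueError):
    """Efficiency is undefined for a session with zero responses."""
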