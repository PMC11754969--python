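"""Exception hierarchy shared across the package."""


class HRVStressError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(HRVStressError, ValueError):
    """Invalid configuration (cohort parameters, pipeline options)."""


class SimulationError(HRVStressError, RuntimeError):
    """The RRI generator produced a physiologically impossible beat."""


class QualityError(HRVStressError, ValueError):
    """An RRI series failed artifact-quality screening."""


class InsufficientDataError(HRVStressError, ValueError):
    """Too few beats / samples for the requested computation."""


class ParseError(HRVStressError, ValueError):
    """Malformed input table."""
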