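"""Exception hierarchy shared across the package."""


class ArmBiomechError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(ArmBiomechError, ValueError):
    """An argument violates a documented precondition."""


class InsufficientDataError(ArmBiomechError, ValueError):
    """Too few samples to compute the requested quantity."""


class ConfigurationError(ArmBiomechError, ValueError):
    """A configuration value is missing or inconsistent."""


class SegmentationError(ArmBiomechError, ValueError):
    """Frame count is inconsistent with the tempo / beat-count contract."""


class UndefinedCorrelationError(ArmBiomechError, ValueError):
    """Correlation is undefined (zero variance in one of the variables)."""
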