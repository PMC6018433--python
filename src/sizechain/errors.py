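"""Exception hierarchy for sizechain."""


class SizechainError(Exception):
    """Base class for all sizechain errors."""


class ConfigurationError(SizechainError, ValueError):
    """Invalid configuration, e.g. an unknown division-pattern identifier."""


class DomainError(SizechainError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class NumericalError(SizechainError, RuntimeError):
    """A numerical procedure failed to reach its tolerance."""


class DegenerateSampleError(SizechainError, ValueError):
    """A data sample is empty or otherwise unusable after filtering."""


class PeakNotFoundError(SizechainError, RuntimeError):
    """No interior spectral peak above the zero-mode shoulder."""


class FitDegenerateError(SizechainError, RuntimeError):
    """The fitting objective is flat: the data do not constrain the parameter."""


class EmptyStatisticsError(SizechainError, ValueError):
    """A trajectory contains no post-burn-in division events."""
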