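"""Exception and warning types shared across the package."""

from __future__ import annotations


class DomainError(ValueError):
    """An input lies outside the mathematical domain of an operation."""


class OutOfDomainError(DomainError):
    """A normalized leaf rank falls outside every declared piece interval.

    Carries the valid intervals so callers can report where predictions
    are defined.
    """

    def __init__(self, message: str, intervals=()):
        super().__init__(message)
        self.intervals = tuple(intervals)


class SchemaError(ValueError):
    """A table does not match the expected observation schema."""


class ConfigError(ValueError):
    """A configuration file contains unknown or invalid keys."""


class FitError(RuntimeError):
    """A regression could not be estimated (singular design, too few points...)."""


class EffectContractError(ValueError):
    """A phenology effect function returned a value outside [0, 1]."""


class ClampedValueWarning(UserWarning):
    """A model prediction was clamped back into its physical range."""


class ClippedPredictionWarning(UserWarning):
    """A negative partitioning-coefficient prediction was clipped to zero."""
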