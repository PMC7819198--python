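"""Exception hierarchy for the alarm pipeline."""


class CgmAlarmError(Exception):
    """Base class for all package errors."""


class InvalidMeasurementError(CgmAlarmError):
    """A glucose value is non-finite or non-positive."""


class ConfigurationError(CgmAlarmError):
    """A parameter value violates the pipeline's contracts."""


class EmptyLibraryError(CgmAlarmError):
    """No alarm events were found at a level, so no library can be built."""

    def __init__(self, level: str, message: str | None = None):
        self.level = level
        super().__init__(message or f"no alarm events at level {level}: cannot build a pattern library")


class UndefinedMetricError(CgmAlarmError):
    """A ratio metric was requested with a zero denominator."""


class LcsOverflowError(CgmAlarmError):
    """The number of distinct longest common subsequences exceeded the guard cap."""
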