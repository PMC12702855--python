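"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`StrokekinError`, so callers can
distinguish pipeline failures from programming errors.
"""


class StrokekinError(Exception):
    """Base class for all pipeline errors."""


class InvalidIntervalError(StrokekinError, ValueError):
    """A time interval with t1 <= t0."""


class SamplingError(StrokekinError, ValueError):
    """Non-uniform time base or sampling rate too low for the requested analysis."""


class NoMovementError(StrokekinError, ValueError):
    """Speed profile never exceeds the detection threshold."""


class SegmentationError(StrokekinError, RuntimeError):
    """Fewer qualifying speed peaks than phases requested.

    Attributes
    ----------
    n_peaks_found : int
        Number of qualifying peaks detected before giving up.
    """

    def __init__(self, message: str, n_peaks_found: int):
        super().__init__(message)
        self.n_peaks_found = n_peaks_found


class UndefinedMetricError(StrokekinError, ValueError):
    """A biomarker is undefined on the given window (all-zero signal, constant angle, ...)."""


class WindowError(StrokekinError, ValueError):
    """Requested window lies outside the recorded time span."""


class DomainError(StrokekinError, ValueError):
    """Input values outside the metric's domain (e.g. negative muscle force)."""


class InsufficientDataError(StrokekinError, ValueError):
    """Too few observations for the requested statistic."""


class DegenerateDataError(StrokekinError, ValueError):
    """Zero-variance input where a scale estimate is required."""


class ConfigurationError(StrokekinError, ValueError):
    """Invalid or inconsistent configuration."""


class SchemaError(StrokekinError, ValueError):
    """A file or table does not conform to the documented schema."""


class LeakageError(StrokekinError, ValueError):
    """Development and test cohorts share subject ids."""
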