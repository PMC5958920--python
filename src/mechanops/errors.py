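"""Exception hierarchy.

Every error raised by the package derives from :class:`MechanopsError`, so
callers can catch one base class at pipeline boundaries while the library
still distinguishes configuration, format, physics-domain and signal
problems.
"""


class MechanopsError(Exception):
    """Base class for all package errors."""


class ConfigError(MechanopsError):
    """A configuration file is missing a mandatory key or cannot be parsed."""


class ValidationError(MechanopsError):
    """A domain object violates one of its declared invariants."""


class TraceFormatError(MechanopsError):
    """A trace file is malformed (non-uniform time base, NaN samples, ...)."""


class ParameterError(MechanopsError):
    """An analysis parameter is out of its admissible range."""


class BaselineError(MechanopsError):
    """No usable baseline segment could be found in a trace."""


class SegmentationError(MechanopsError):
    """An event window cannot be segmented against the device geometry."""


class InconsistentEventError(SegmentationError):
    """A segmented event violates pulse anatomy (e.g. contraction drop not deepest)."""


class DomainError(MechanopsError):
    """A physics formula was evaluated outside its mathematical domain."""


class CalibrationError(MechanopsError):
    """Effective-diameter calibration has no admissible solution."""


class InfeasibleCellError(MechanopsError):
    """A simulated cell is too large for the channel's effective diameter."""


class DurationError(MechanopsError):
    """Simulated events do not fit inside the requested trace duration."""


class DegenerateEventError(MechanopsError):
    """A pulse record has a zero-duration sub-pulse or similar degeneracy."""


class InsufficientDataError(MechanopsError):
    """Too few observations for the requested population statistic."""


class DegenerateTableError(MechanopsError):
    """A contingency table has an empty margin."""
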