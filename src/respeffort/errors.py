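"""Exception hierarchy.

Every error raised by the package derives from :class:`RespEffortError`
so callers can catch the whole family with one clause.
"""


class RespEffortError(Exception):
    """Base class for all package errors."""


class ValidationError(RespEffortError):
    """A recording violates its structural invariants."""


class MissingChannel(ValidationError):
    """A required channel column is absent from a channel file."""


class GridError(ValidationError):
    """The time grid is not uniform within tolerance."""


class FormatError(RespEffortError):
    """A channel file row could not be parsed."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(message if line is None else f"line {line}: {message}")


class SimulationError(RespEffortError):
    """The waveform integrator produced non-finite values."""


class PlacementError(RespEffortError):
    """An occlusion hold could not be placed in a stable breath phase."""


class ParameterError(RespEffortError):
    """An argument is outside its documented domain."""


class WindowError(RespEffortError):
    """A detection window is too short for the requested measurement."""


class OnsetMissing(RespEffortError):
    """The breath has no detected inspiratory-effort onset."""


class DataError(RespEffortError):
    """Required data are absent or empty."""


class LevelSkipped(DataError):
    """No eligible breaths in the averaging window; the level is skipped."""


class LevelMissing(DataError):
    """No accepted occlusion maneuver at this support level."""


class ManeuverTooShort(RespEffortError):
    """The occlusion hold is too short for the requested index."""


class QCRejected(RespEffortError):
    """The maneuver failed quality control; carries the QC status."""

    def __init__(self, status: str):
        self.status = status
        super().__init__(f"maneuver rejected by QC: {status}")


class DegenerateLabels(RespEffortError):
    """A binary-label vector contains a single class."""


class SampleTooSmall(RespEffortError):
    """Not enough observations for a nonparametric reference interval."""


class GroupingError(RespEffortError):
    """Degenerate patient grouping for the variance decomposition."""


class ConfigError(RespEffortError):
    """Pipeline configuration violates its schema."""
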