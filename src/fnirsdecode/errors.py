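"""Exception hierarchy shared across the pipeline stages."""


class FnirsError(Exception):
    """Base class for all package-specific errors."""


class FormatError(FnirsError):
    """An on-disk artifact is structurally malformed (missing file/column/group)."""


class ValidationError(FnirsError, ValueError):
    """An in-memory object violates a domain invariant (e.g. nonpositive intensity)."""


class ScheduleError(FnirsError):
    """A simulated trial schedule does not fit into the requested record."""


class SegmentationError(FnirsError):
    """A trial window falls outside the bounds of the recording."""


class FilterLengthError(FnirsError):
    """The record is too short for the designed FIR filter."""


class FitError(FnirsError):
    """A classifier fit is impossible (single class, too few trials)."""
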