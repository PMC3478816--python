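"""Exception hierarchy for the gaitslope pipeline.

Every stage raises a subclass of :class:`GaitSlopeError` so callers can
catch pipeline failures without masking programming errors.
"""


class GaitSlopeError(Exception):
    """Base class for all gaitslope errors."""


class FormatError(GaitSlopeError):
    """Input file is malformed (missing columns, unparseable values)."""


class SamplingError(GaitSlopeError):
    """Time base is not uniform enough to treat as a fixed-rate recording."""


class DataError(GaitSlopeError):
    """Signal content violates a recording invariant (NaN/Inf, too short)."""


class ValidationError(GaitSlopeError):
    """A domain object failed its invariants at construction time."""


class FilterError(GaitSlopeError):
    """Signal too short (or cutoff invalid) for zero-phase filtering."""


class DetectionError(GaitSlopeError):
    """Gait-event detection failed (no swing peaks / no lower lobes)."""


class InsufficientDataError(GaitSlopeError):
    """Fewer than two mid-stance events: no complete stride available."""


class OrientationError(GaitSlopeError):
    """Accelerometer tilt initialization impossible (sensor not upright)."""


class CalibrationError(GaitSlopeError):
    """Linear calibration could not be fitted or inverted."""


class EvaluationError(GaitSlopeError):
    """Metric computation failed (missing truth, empty/degenerate groups)."""


class ConstructionError(GaitSlopeError):
    """Synthetic scenario cannot satisfy its mid-stance stationarity
    constraints; the message names the violated constraint."""
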