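"""Exception hierarchy for the lactoscan pipeline.

All validation-style failures derive from :class:`ValidationError` so batch
drivers can distinguish bad inputs (exit code 2) from stage crashes (3).
"""


class LactoscanError(Exception):
    """Base class for all package errors."""


class ValidationError(LactoscanError, ValueError):
    """Input violates a documented invariant or schema."""


class InsufficientCalibrationError(ValidationError):
    """Fewer than two distinct calibration standards supplied."""


class InvalidCalibrationError(ValidationError):
    """Calibration parameters outside their physical range (e.g. gain <= 0)."""


class OutOfRangeTemperatureError(ValidationError):
    """Temperature so far from 25 degC that the linear compensation degenerates."""


class SchemaError(ValidationError):
    """A CSV is missing mandatory columns; message names them."""


class EmptyChartError(ValidationError):
    """No day bin had enough records to emit a percentile."""


class UndefinedSensitivityError(ValidationError):
    """No positive-class records inside the evaluation day window."""


class InsufficientDataError(ValidationError):
    """Too few scans (or too short a span) to fit activation kinetics."""


class StageError(LactoscanError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
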