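"""Exception hierarchy for myoturnover."""


class MyoturnoverError(Exception):
    """Base class for all package errors."""


class InvalidConfigurationError(MyoturnoverError):
    """A geometry/kinetics/render configuration violates its invariants."""


class CalibrationError(MyoturnoverError):
    """Kinetics calibration could not reproduce the requested anchors."""

    def __init__(self, message: str, residuals=None):
        super().__init__(message)
        self.residuals = residuals


class DegenerateTraceError(MyoturnoverError):
    """A FRAP trace has zero dynamic range between pre and post frames."""


class CorrectionWindowError(MyoturnoverError):
    """The red drift-correction window contains too few samples."""


class InsufficientDataError(MyoturnoverError):
    """Too few converged fits (or samples) for the requested statistic."""


class BoundaryError(MyoturnoverError):
    """A sarcomere is truncated at the scan edge; no flanking minima exist."""


class CategoryError(MyoturnoverError):
    """An operation was applied to an incompatible pattern category."""


class PipelineValidationError(MyoturnoverError):
    """A pipeline configuration failed schema validation."""

    def __init__(self, message: str, keys=None):
        super().__init__(message)
        self.keys = list(keys or [])
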