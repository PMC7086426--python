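"""Exception hierarchy shared across the pipeline."""


class EEGTBIError(Exception):
    """Base class for all package errors."""


class FormatError(EEGTBIError):
    """A file could not be parsed in the declared format."""


class MontageError(EEGTBIError):
    """Channel bookkeeping violated (missing label, bad exclusion)."""


class InsufficientDataError(EEGTBIError):
    """A recording is too short for the requested operation."""


class ShapeError(EEGTBIError):
    """A feature map or input shape is invalid for a layer."""


class PlanError(EEGTBIError):
    """A cross-validation fold plan is inconsistent with the cohort."""


class UndefinedMetricError(EEGTBIError):
    """A metric is requested on an empty or degenerate input."""


class FrequencyError(EEGTBIError):
    """A frequency band is incompatible with the sampling rate."""


class TrainingError(EEGTBIError):
    """Training preconditions violated (e.g. single-class input)."""


class ValidationError(EEGTBIError):
    """A run configuration failed schema validation."""
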