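"""Exception hierarchy shared across the pipeline stages."""


class SeropanelError(Exception):
    """Base class for all package-specific errors."""


class MatrixFormatError(SeropanelError):
    """Malformed analyte matrix file (bad cell, duplicate id, non-positive value)."""


class AnnotationFormatError(SeropanelError):
    """Malformed sample annotation file or cross-field invariant violation."""


class ConfigError(SeropanelError):
    """Invalid configuration (overlapping marker sets, bad thresholds, ...)."""


class DegenerateSampleError(SeropanelError):
    """Too few (distinct) values to fit a distribution."""


class ScoringError(SeropanelError):
    """A sample cannot be scored by a classifier (missing analyte, bad value)."""


class TrainingError(SeropanelError):
    """Classifier training failed (absent class, empty panel)."""


class SelectionError(SeropanelError):
    """Biomarker selection could not produce any candidates."""


class GateError(SeropanelError):
    """A criteria gate referenced a metric that is absent on a panel."""


class UnblindingError(SeropanelError):
    """A verification barcode is missing from the blinding key."""
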