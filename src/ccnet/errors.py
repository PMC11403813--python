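"""Exception hierarchy shared across the package."""


class CCNetError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CCNetError):
    """A file does not conform to the expected dialect (e.g. missing columns)."""


class ValidationError(CCNetError):
    """A record fails row- or field-level validation."""


class PreprocessingError(CCNetError):
    """Normalization / filtering cannot proceed on the given matrix."""


class StageError(CCNetError):
    """A matrix is at the wrong processing stage for the requested operation."""


class AnnotationError(CCNetError):
    """Cell barcodes and annotation do not align."""


class GeneLookupError(CCNetError):
    """A gene or cell type is missing from a summary."""


class AlignmentError(CCNetError):
    """Two indexed objects do not share compatible axes."""


class ConvergenceError(CCNetError):
    """An iterative solver failed to converge within its iteration budget."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class PipelineError(CCNetError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage
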