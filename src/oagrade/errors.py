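"""Exception hierarchy shared across the pipeline stages."""


class OAGradeError(Exception):
    """Base class for all package errors."""


class InvalidGradeError(OAGradeError, ValueError):
    """A KL grade outside {0..4} (or outside a scheme's range) was supplied."""


class InvalidGeometryError(OAGradeError, ValueError):
    """Image geometry is inconsistent (gap wider than image, tile grid too big, ...)."""


class InvalidInputError(OAGradeError, ValueError):
    """Malformed input data (empty image, shape mismatch, label out of range)."""


class InvalidSplitError(OAGradeError, ValueError):
    """A split specification would produce an empty or overlapping partition."""


class ConfigurationError(OAGradeError, ValueError):
    """Invalid configuration value (unknown scheme, bad class count, ...)."""


class ArchitectureError(OAGradeError, ValueError):
    """A requested layer does not exist in the model."""


class DivergenceError(OAGradeError, RuntimeError):
    """Training produced a non-finite loss."""


class StageError(OAGradeError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")
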