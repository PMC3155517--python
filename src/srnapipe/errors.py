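"""Shared exception types."""


class FormatError(ValueError):
    """Malformed record in an input file (message names file and line)."""


class ValidationError(ValueError):
    """Annotation inconsistent with the sequences it refers to."""


class ConfigurationError(ValueError):
    """Invalid or infeasible configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause
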