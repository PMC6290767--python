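"""Exception hierarchy shared across the pipeline."""


class ExomirError(Exception):
    """Base class for all package errors."""


class ParseError(ExomirError):
    """A file could not be parsed (malformed row, empty file, ...)."""


class ValidationError(ExomirError, ValueError):
    """Input violates a documented invariant (negative count, duplicate id, ...)."""


class JoinError(ExomirError):
    """Count matrix and metadata do not describe the same samples."""


class EmptyCohortError(ExomirError):
    """A filter removed every sample."""


class StageError(ExomirError):
    """A pipeline stage failed; carries the stage name for context."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
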