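"""Exception hierarchy shared across the package."""


class CommvadeError(Exception):
    """Base class for all package errors."""


class FormatError(CommvadeError):
    """A file could not be parsed in the declared format."""


class ValidationError(CommvadeError):
    """Parsed data violates a structural invariant."""


class ConfigurationError(CommvadeError):
    """An analysis was requested with an unusable configuration."""


class StageError(CommvadeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
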