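"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: configuration errors exit 2, data
validation errors exit 3, stage failures exit 4.
"""

from __future__ import annotations


class TamtalkError(Exception):
    """Base class for all package errors."""


class InputError(TamtalkError):
    """A single bad argument or malformed input value."""


class ConfigError(TamtalkError):
    """Invalid configuration; carries the full list of problems at once."""

    def __init__(self, errors: list[str] | str):
        if isinstance(errors, str):
            errors = [errors]
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


class DataValidationError(TamtalkError):
    """An input table violates a contract (missing column, bad value, bad join)."""


class StageError(TamtalkError):
    """A pipeline stage failed; tags the originating stage."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
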