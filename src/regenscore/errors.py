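"""Exception hierarchy shared across the package."""


class RegenError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(RegenError):
    """A practice map or configuration file failed validation."""


class LoadError(RegenError):
    """A data table could not be loaded; carries the offending row when known."""

    def __init__(self, message: str, row: int | None = None):
        if row is not None:
            message = f"{message} (row {row})"
        super().__init__(message)
        self.row = row


class ScoreError(RegenError):
    """A score is undefined for the given inputs."""


class FitError(RegenError):
    """A statistical fit cannot be performed on the given inputs."""
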