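"""Exception hierarchy shared across the toolkit."""


class RemoteEEGError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(RemoteEEGError):
    """A session configuration failed validation; the message names the field."""


class FormatError(RemoteEEGError):
    """A recording archive does not conform to the documented format."""


class SessionTruncationError(RemoteEEGError):
    """The sample source was exhausted before the session finished."""

    def __init__(self, message: str, last_completed_task: int | None = None):
        super().__init__(message)
        self.last_completed_task = last_completed_task


class ConvergenceError(RemoteEEGError):
    """An iterative solver did not reach its tolerance."""

    def __init__(self, message: str, final_norm: float | None = None):
        super().__init__(message)
        self.final_norm = final_norm
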