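"""Exception hierarchy shared by all lfpsync modules.

Configuration problems (bad parameters, impossible schedules) raise
:class:`ConfigError`; problems with the data itself (too short, degenerate,
missing channels) raise :class:`DataError` subclasses.
"""


class LfpsyncError(Exception):
    """Base class for all package errors."""


class ConfigError(LfpsyncError, ValueError):
    """Invalid configuration or parameter value."""


class ScheduleError(ConfigError):
    """Scheduled event intervals overlap or fall outside the session."""


class DataError(LfpsyncError, ValueError):
    """Input data violates an operation's preconditions."""


class InsufficientDataError(DataError):
    """Signal or sample set too short for the requested analysis."""


class DegenerateSignalError(DataError):
    """All-zero, constant, or zero-variance input where variation is required."""


class IncompleteMontageError(DataError):
    """A montage channel is missing or was excluded by screening."""

    def __init__(self, channel: str, reason: str = "missing"):
        self.channel = channel
        super().__init__(f"montage channel {channel!r} unavailable: {reason}")
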