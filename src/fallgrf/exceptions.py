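"""Exception hierarchy.

Everything raised on purpose by this package derives from :class:`FallGrfError`,
so callers can catch one type at pipeline level while still seeing ``ValueError``
semantics from the standard library's point of view.
"""


class FallGrfError(Exception):
    """Base class for all errors raised by fallgrf."""


class ParameterError(FallGrfError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateSeriesError(FallGrfError, ValueError):
    """A series cannot be standardized (too short or zero variance)."""


class MissingChannelError(FallGrfError, ValueError):
    """A subject lacks a recording for a required GRF channel."""

    def __init__(self, channel: str, subject_id: str = ""):
        self.channel = channel
        self.subject_id = subject_id
        msg = f"missing recording for channel {channel!r}"
        if subject_id:
            msg += f" (subject {subject_id!r})"
        super().__init__(msg)


class UndefinedEntropyError(FallGrfError, ValueError):
    """Sample entropy is undefined (no template matches) for a channel."""

    def __init__(self, channel: str, subject_id: str = ""):
        self.channel = channel
        self.subject_id = subject_id
        msg = f"sample entropy undefined for channel {channel!r}"
        if subject_id:
            msg += f" (subject {subject_id!r})"
        super().__init__(msg)


class CalibrationError(FallGrfError, RuntimeError):
    """An entropy target cannot be met by the generative family."""


class FoldError(FallGrfError, RuntimeError):
    """A leave-one-out training fold lost a class entirely."""


class ConfigError(FallGrfError, ValueError):
    """A pipeline configuration is invalid."""
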