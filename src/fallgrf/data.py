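"""Domain containers: GRF recordings, subjects, and the fixed channel layout.

The analysis consumes eight channels per subject: six walking ground-reaction-force
components (medial-lateral, anterior-posterior and superior-inferior, for each
foot) and two sit-to-stand vertical force channels (one per foot). The order of
``CHANNELS`` is the canonical feature order used by every downstream table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ParameterError

ACTIVITY_WALKING = "walking"
ACTIVITY_STS = "sts"

GROUP_FALLER = "faller"
GROUP_NONFALLER = "nonfaller"
#: Faller first: it is the positive class and wins score ties.
GROUP_ORDER = (GROUP_FALLER, GROUP_NONFALLER)

WALKING_AXES = ("ML", "AP", "SI")
STS_AXES = ("V",)


@dataclass(frozen=True)
class Channel:
    """One GRF channel: activity, foot and force axis, with its short name."""

    name: str
    activity: str
    foot: str
    axis: str


CHANNELS: tuple[Channel, ...] = (
    Channel("L_ML_F", ACTIVITY_WALKING, "left", "ML"),
    Channel("L_AP_F", ACTIVITY_WALKING, "left", "AP"),
    Channel("L_SI_F", ACTIVITY_WALKING, "left", "SI"),
    Channel("R_ML_F", ACTIVITY_WALKING, "right", "ML"),
    Channel("R_AP_F", ACTIVITY_WALKING, "right", "AP"),
    Channel("R_SI_F", ACTIVITY_WALKING, "right", "SI"),
    Channel("L_V_F", ACTIVITY_STS, "left", "V"),
    Channel("R_V_F", ACTIVITY_STS, "right", "V"),
)

FEATURE_NAMES: tuple[str, ...] = tuple(c.name for c in CHANNELS)
CHANNEL_BY_NAME: dict[str, Channel] = {c.name: c for c in CHANNELS}


@dataclass
class GrfRecording:
    """A single force channel's time series for one subject.

    ``series`` holds force samples (Newtons in raw data; any affine rescaling
    is irrelevant to the entropy features because standardization precedes
    them). Walking recordings carry one of the three force axes; sit-to-stand
    recordings carry the vertical axis only.
    """

    subject_id: str
    activity: str
    foot: str
    axis: str
    series: np.ndarray

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=float)
        if self.series.ndim != 1:
            raise ParameterError("recording series must be one-dimensional")
        if self.activity == ACTIVITY_WALKING:
            if self.axis not in WALKING_AXES:
                raise ParameterError(
                    f"walking recordings use axes {WALKING_AXES}, got {self.axis!r}"
                )
        elif self.activity == ACTIVITY_STS:
            if self.axis not in STS_AXES:
                raise ParameterError(
                    f"sit-to-stand recordings use axis 'V', got {self.axis!r}"
                )
        else:
            raise ParameterError(f"unknown activity {self.activity!r}")
        if self.foot not in ("left", "right"):
            raise ParameterError(f"foot must be 'left' or 'right', got {self.foot!r}")

    @property
    def channel_name(self) -> str:
        prefix = "L" if self.foot == "left" else "R"
        return f"{prefix}_{self.axis}_F"

    def __len__(self) -> int:
        return self.series.size


@dataclass
class Subject:
    """A study participant: label, body weight and their GRF recordings."""

    subject_id: str
    group: str
    weight_kg: float
    recordings: list[GrfRecording] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.weight_kg <= 0:
            raise ParameterError("body weight must be positive")

    def recordings_for(self, channel: Channel | str) -> list[GrfRecording]:
        """All recordings of one channel (possibly several trials)."""
        name = channel if isinstance(channel, str) else channel.name
        return [r for r in self.recordings if r.channel_name == name]


@dataclass
class FeatureVector:
    """The eight per-channel sample-entropy values, in ``FEATURE_NAMES`` order."""

    subject_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(FEATURE_NAMES),):
            raise ParameterError(
                f"feature vector must have {len(FEATURE_NAMES)} entries"
            )

    def as_dict(self) -> dict[str, float]:
        return dict(zip(FEATURE_NAMES, self.values.tolist()))
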