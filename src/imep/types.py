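"""Core domain types shared across the pipeline.

All containers are plain dataclasses with eager validation: an object that
constructs is an object the rest of the pipeline may trust. Units follow the
conventions used throughout the package: forces in N, moments in N·m, COP and
marker positions in cm, leg length in cm, height in m, weight in kg.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

TEST_TYPES = ("SLB", "TBT", "YBT")
EYES = ("open", "closed", "n/a")
FEET = ("right", "left", "both")
YBT_DIRECTIONS = ("anterior", "posteromedial", "posterolateral")
SCORING_MARKERS = ("acromion", "umbilicus", "trochanter")
MARKERS = SCORING_MARKERS + ("L3",)

#: Protocol slot counts per test: SLB 2 eye conditions x 2 legs, TBT likewise,
#: YBT 3 directions x 2 legs — 14 recorded attempts per participant in total.
EXERCISES_PER_TEST = {"SLB": 4, "TBT": 4, "YBT": 6}


class ImepError(Exception):
    """Base class for all validation and protocol errors raised here."""


class FormatError(ImepError):
    """A file does not conform to the expected external format."""


class ProtocolError(ImepError):
    """Trial/exercise structure does not match the 14-slot protocol."""


def _require(condition: bool, message: str, exc: type = ValueError) -> None:
    if not condition:
        raise exc(message)


@dataclass
class ParticipantProfile:
    """Demographics that drive the correction factor and YBT normalization.

    ``sex``, ``age`` (years) and ``foot_size`` (EU) feed the demographic
    correction regression; ``leg_length`` (cm) normalizes YBT reaches.
    """

    nickname: str
    sex: str
    age: float
    foot_size: float
    leg_length: float
    dominant_foot: str = "right"
    height: Optional[float] = None
    weight: Optional[float] = None

    def __post_init__(self) -> None:
        _require(bool(self.nickname), "nickname must be non-empty")
        _require(self.sex in ("female", "male"), f"sex must be female/male, got {self.sex!r}")
        _require(self.age > 0, "age must be positive")
        _require(self.foot_size > 0, "foot_size must be positive")
        _require(self.leg_length > 0, "leg_length must be positive")
        _require(
            self.dominant_foot in ("right", "left"),
            f"dominant_foot must be right/left, got {self.dominant_foot!r}",
        )

    @property
    def is_male(self) -> bool:
        return self.sex == "male"


@dataclass
class PlateTrial:
    """One balance attempt's six-channel force/moment record plus metadata.

    Channels are equal-length 1-D arrays: Fx, Fy, Fz in N and Mx, My, Mz in
    N·m, sampled at ``sampling_rate`` Hz. Static trials (SLB/TBT) are
    nominally 16 s; YBT trials nominally 5 s.
    """

    participant: str
    test_type: str
    eyes: str
    support_foot: str
    sampling_rate: float
    fx: np.ndarray
    fy: np.ndarray
    fz: np.ndarray
    mx: np.ndarray
    my: np.ndarray
    mz: np.ndarray
    ybt_direction: str = "n/a"
    nominal_duration: Optional[float] = None

    def __post_init__(self) -> None:
        _require(self.test_type in TEST_TYPES, f"unknown test_type {self.test_type!r}")
        _require(self.eyes in EYES, f"unknown eyes condition {self.eyes!r}")
        _require(self.support_foot in FEET, f"unknown support_foot {self.support_foot!r}")
        _require(
            self.ybt_direction in YBT_DIRECTIONS + ("n/a",),
            f"unknown ybt_direction {self.ybt_direction!r}",
        )
        _require(self.sampling_rate > 0, "sampling_rate must be positive")
        for name in ("fx", "fy", "fz", "mx", "my", "mz"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.fz)
        _require(
            all(len(getattr(self, c)) == n for c in ("fx", "fy", "mx", "my", "mz")),
            "all six channels must have equal length",
        )
        if self.nominal_duration is None:
            self.nominal_duration = 5.0 if self.test_type == "YBT" else 16.0

    @property
    def n_samples(self) -> int:
        return len(self.fz)

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def channels(self) -> dict[str, np.ndarray]:
        return {
            "Fx": self.fx, "Fy": self.fy, "Fz": self.fz,
            "Mx": self.mx, "My": self.my, "Mz": self.mz,
        }


@dataclass
class MarkerTrack:
    """A single marker's digitized trajectory in calibrated centimetres."""

    marker: str
    x: np.ndarray
    y: np.ndarray
    calibration_cm_per_px: float = 1.0

    def __post_init__(self) -> None:
        _require(self.marker in MARKERS, f"unknown marker {self.marker!r}")
        _require(self.calibration_cm_per_px > 0, "calibration factor must be positive")
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        _require(len(self.x) == len(self.y), "x and y series must have equal length")

    def __len__(self) -> int:
        return len(self.x)


@dataclass
class ScaleDefinition:
    """Everything needed to map a movement total onto the 1-10 scale.

    ``cte`` inverts the static movement total (or offsets the YBT log sum);
    the ``fc_*`` coefficients predict the demographic correction factor;
    ``smoothing`` halves its impact by default; ``adjusted_min``/``adjusted_max``
    are the cohort bounds used in the min-max rescale to [1, 10].
    """

    test_type: str
    cte: float
    fc_intercept: float
    fc_male: float
    fc_age: float
    fc_footsize: float
    adjusted_min: float
    adjusted_max: float
    smoothing: float = 0.5
    log_base: str = "natural"

    def __post_init__(self) -> None:
        _require(self.test_type in TEST_TYPES, f"unknown test_type {self.test_type!r}")
        _require(
            self.adjusted_max > self.adjusted_min,
            "adjusted_max must exceed adjusted_min",
        )
        _require(0 < self.smoothing <= 1, "smoothing must be in (0, 1]")
        _require(self.log_base in ("natural", "base10"), f"unknown log_base {self.log_base!r}")


@dataclass
class ScoreReport:
    """Full audit trail from movement input to final 1-10 score."""

    participant: str
    test_type: str
    input_quantity: float  # total movement (cm) for SLB/TBT, Σ YBT scores for YBT
    raw_score: float
    fc: float
    adjusted_score: float
    final_score: float
    details: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        _require(1.0 <= self.final_score <= 10.0, "final_score must lie in [1, 10]")
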