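"""Movement quantification from marker tracks.

Each exercise is scored from three body markers (acromion, umbilicus,
greater trochanter). Per marker, the deviation along each image axis is the
max-min excursion over the scored window; the marker's displacement combines
the two by the Pythagorean theorem. An exercise's movement (mvt) sums the
three markers; a test's total movement sums its exercises (4 for SLB, 4 for
TBT, 6 for YBT). The L3 marker from the dorsal camera is accepted and can be
reported, but never enters the score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from imep.types import (
    EXERCISES_PER_TEST,
    SCORING_MARKERS,
    MarkerTrack,
    ProtocolError,
)


@dataclass
class ExerciseMovement:
    """Per-marker displacements (cm) and their sum for one protocol slot."""

    exercise_id: int  # protocol slot, 1-14
    per_marker: dict[str, float]
    mvt: float

    def __post_init__(self) -> None:
        if not 1 <= self.exercise_id <= 14:
            raise ValueError("exercise_id must be a protocol slot in 1..14")
        if any(v < 0 for v in self.per_marker.values()) or self.mvt < 0:
            raise ValueError("displacements must be non-negative")


@dataclass
class TestMovement:
    """All exercises of one test and their summed total movement (cm)."""

    test_type: str
    exercises: list[ExerciseMovement]
    total: float


def marker_displacement(
    track: MarkerTrack, window: Optional[tuple[int, int]] = None
) -> float:
    """Displacement (cm): hypot of the x and y max-min excursions.

    The excursion is what an observer notes from a video tracker: how far
    the marker strayed along each axis over the scored window, regardless of
    path taken.
    """
    start, stop = window if window is not None else (0, len(track))
    x = track.x[start:stop]
    y = track.y[start:stop]
    if len(x) == 0:
        raise ValueError("empty window")
    despl_x = float(np.max(x) - np.min(x))
    despl_y = float(np.max(y) - np.min(y))
    return math.hypot(despl_x, despl_y)


def exercise_movement(
    tracks: Mapping[str, MarkerTrack],
    exercise_id: int,
    window: Optional[tuple[int, int]] = None,
) -> ExerciseMovement:
    """Sum the three scoring markers' displacements for one exercise.

    ``tracks`` maps marker name to track; acromion, umbilicus and trochanter
    are required, an L3 entry is tolerated and ignored.
    """
    for marker in SCORING_MARKERS:
        if marker not in tracks:
            raise ValueError(f"marker {marker} required")
    per_marker = {
        marker: marker_displacement(tracks[marker], window)
        for marker in SCORING_MARKERS
    }
    return ExerciseMovement(
        exercise_id=exercise_id,
        per_marker=per_marker,
        mvt=sum(per_marker.values()),
    )


def test_total_movement(
    test_type: str, exercises: Sequence[ExerciseMovement]
) -> TestMovement:
    """Sum exercise movements into a test total; exercise count must match."""
    expected = EXERCISES_PER_TEST.get(test_type)
    if expected is None:
        raise ValueError(f"unknown test_type {test_type!r}")
    if len(exercises) != expected:
        raise ProtocolError(
            f"{test_type} requires {expected} exercises, got {len(exercises)}"
        )
    return TestMovement(
        test_type=test_type,
        exercises=list(exercises),
        total=float(sum(e.mvt for e in exercises)),
    )
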