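"""Readers and writers for every external representation the pipeline touches.

Formats:

* force-plate export — tab-delimited text, one header row naming channels
  (at least ``Fz``, ``Mx``, ``My``; missing ``Fx``/``Fy``/``Mz`` default to
  zero), one row per sample;
* marker track — two-column CSV (x, y) in pixels or cm, converted to cm at
  read time via a calibration factor;
* cohort table — one CSV row per participant;
* scale definition — flat JSON document;
* score report — JSON (single) or CSV (batch).

Every reader/writer pair round-trips valid documents to stored precision and
preserves sample order.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from imep.types import (
    FormatError,
    MarkerTrack,
    ParticipantProfile,
    PlateTrial,
    ScaleDefinition,
    ScoreReport,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

#: Default sampling rate assumed when neither the file nor the caller
#: provides one. Typical for the portable-platform class used here; always
#: overridable and recorded in downstream reports.
DEFAULT_SAMPLING_RATE = 1000.0

_REQUIRED_CHANNELS = ("Fz", "Mx", "My")
_ALL_CHANNELS = ("Fx", "Fy", "Fz", "Mx", "My", "Mz")
_COHORT_REQUIRED = ("nickname", "sex", "age", "foot_size", "leg_length")

_SCALE_FIELDS = {
    "test_type", "cte", "fc_intercept", "fc_male", "fc_age", "fc_footsize",
    "adjusted_min", "adjusted_max", "smoothing", "log_base",
}
_SCALE_OPTIONAL = {"smoothing", "log_base"}


# ---------------------------------------------------------------------------
# force-plate export

def read_plate_export(
    path: PathLike,
    *,
    participant: str = "unknown",
    test_type: str = "SLB",
    eyes: str = "n/a",
    support_foot: str = "right",
    ybt_direction: str = "n/a",
    sampling_rate: Optional[float] = None,
    column_map: Optional[dict[str, str]] = None,
) -> PlateTrial:
    """Parse a tab/whitespace-delimited plate export into a PlateTrial.

    The header must name at least Fz, Mx and My; a ``# sampling_rate: <Hz>``
    comment line, if present, supplies the rate, else ``sampling_rate`` or
    the package default is used. ``column_map`` renames vendor headers to
    canonical channel names (e.g. ``{"Force Z": "Fz"}``). Trial metadata not
    stored in the file comes from keyword arguments; it is never guessed
    from the filename.
    """
    path = Path(path)
    header_rate = None
    header_line = ""
    skip = 0
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                skip += 1
                if "sampling_rate" in line:
                    header_rate = float(line.split(":", 1)[1])
            else:
                header_line = line
                break
    try:
        if "\t" in header_line:
            # C engine parses floats to full round-trip precision
            frame = pd.read_csv(path, sep="\t", skiprows=skip, comment="#",
                                float_precision="round_trip")
        else:
            frame = pd.read_csv(path, sep=r"\s+", skiprows=skip, comment="#")
    except (pd.errors.ParserError, ValueError) as exc:
        raise FormatError(f"{path}: cannot parse plate export: {exc}") from exc
    if column_map:
        frame = frame.rename(columns=column_map)
    frame.columns = [str(c).strip() for c in frame.columns]

    for channel in _REQUIRED_CHANNELS:
        if channel not in frame.columns:
            raise FormatError(f"{path}: required channel {channel} absent")
    for channel in _ALL_CHANNELS:
        if channel not in frame.columns:
            frame[channel] = 0.0
        bad = pd.to_numeric(frame[channel], errors="coerce")
        if bad.isna().any():
            row = int(np.flatnonzero(bad.isna())[0])
            raise FormatError(
                f"{path}: non-numeric value in column {channel}, data line {row + 1}"
            )
        frame[channel] = bad

    rate = header_rate if header_rate is not None else sampling_rate
    if rate is None:
        rate = DEFAULT_SAMPLING_RATE
        logger.info("%s: no sampling rate given; assuming %g Hz", path, rate)
    return PlateTrial(
        participant=participant,
        test_type=test_type,
        eyes=eyes,
        support_foot=support_foot,
        ybt_direction=ybt_direction,
        sampling_rate=float(rate),
        fx=frame["Fx"].to_numpy(),
        fy=frame["Fy"].to_numpy(),
        fz=frame["Fz"].to_numpy(),
        mx=frame["Mx"].to_numpy(),
        my=frame["My"].to_numpy(),
        mz=frame["Mz"].to_numpy(),
    )


def write_plate_export(trial: PlateTrial, path: PathLike) -> None:
    """Write a trial as a tab-delimited export with a sampling-rate comment."""
    path = Path(path)
    t = np.arange(trial.n_samples) / trial.sampling_rate
    frame = pd.DataFrame({"t": t, **trial.channels()})
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# sampling_rate: {trial.sampling_rate!r}\n")
        frame.to_csv(fh, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# marker tracks

def read_marker_track(
    path: PathLike, marker: str, calibration_cm_per_px: float = 1.0
) -> MarkerTrack:
    """Read a two-column (x, y) CSV and express positions in cm.

    Pixel coordinates are multiplied by ``calibration_cm_per_px`` (derived in
    practice from reference marks of known length visible in the video).
    Pass 1.0 when the file already stores centimetres.
    """
    if calibration_cm_per_px <= 0:
        raise ValueError("calibration_cm_per_px must be positive")
    path = Path(path)
    frame = pd.read_csv(path, comment="#", float_precision="round_trip")
    if not {"x", "y"} <= set(frame.columns):
        raise FormatError(f"{path}: expected columns x,y; found {list(frame.columns)}")
    x = pd.to_numeric(frame["x"], errors="coerce")
    y = pd.to_numeric(frame["y"], errors="coerce")
    # a shorter column appears as trailing NaNs after pandas pads the rows
    if x.isna().sum() != y.isna().sum():
        raise FormatError(f"{path}: x and y columns differ in length")
    if x.isna().any() or y.isna().any():
        raise FormatError(f"{path}: non-numeric coordinate value")
    return MarkerTrack(
        marker=marker,
        x=x.to_numpy() * calibration_cm_per_px,
        y=y.to_numpy() * calibration_cm_per_px,
        calibration_cm_per_px=1.0,  # already applied
    )


def write_marker_track(track: MarkerTrack, path: PathLike) -> None:
    """Write a marker track as an x,y CSV in cm (calibration pre-applied)."""
    pd.DataFrame({"x": track.x, "y": track.y}).to_csv(
        path, index=False, float_format="%.17g"
    )


# ---------------------------------------------------------------------------
# cohort tables

def read_cohort_table(path: PathLike) -> list[ParticipantProfile]:
    """Read one participant per CSV row; nicknames must be unique.

    Ages outside the instrument's 6-9 year target window produce a warning,
    not an error — the scale may still be applied outside the derivation
    cohort's range (scores clamp to [1, 10]).
    """
    path = Path(path)
    frame = pd.read_csv(path)
    missing = [c for c in _COHORT_REQUIRED if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {', '.join(missing)}")
    dupes = frame["nickname"].astype(str)[frame["nickname"].astype(str).duplicated()]
    if len(dupes):
        raise FormatError(f"{path}: duplicate nickname(s): {sorted(set(dupes))}")
    profiles = []
    for _, row in frame.iterrows():
        age = float(row["age"])
        if not 6.0 <= age <= 9.0:
            warnings.warn(
                f"participant {row['nickname']!r}: age {age:g} outside the "
                "6-9 year target range",
                stacklevel=2,
            )
        kwargs = {}
        for opt in ("height", "weight"):
            if opt in frame.columns and pd.notna(row[opt]):
                kwargs[opt] = float(row[opt])
        if "dominant_foot" in frame.columns and pd.notna(row["dominant_foot"]):
            kwargs["dominant_foot"] = str(row["dominant_foot"])
        profiles.append(
            ParticipantProfile(
                nickname=str(row["nickname"]),
                sex=str(row["sex"]),
                age=age,
                foot_size=float(row["foot_size"]),
                leg_length=float(row["leg_length"]),
                **kwargs,
            )
        )
    return profiles


def write_cohort_table(profiles: Sequence[ParticipantProfile], path: PathLike) -> None:
    pd.DataFrame(
        [
            {
                "nickname": p.nickname,
                "sex": p.sex,
                "age": p.age,
                "foot_size": p.foot_size,
                "leg_length": p.leg_length,
                "dominant_foot": p.dominant_foot,
                "height": p.height,
                "weight": p.weight,
            }
            for p in profiles
        ]
    ).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# scale definitions

def read_scale(path: PathLike) -> ScaleDefinition:
    """Read a ScaleDefinition JSON document; unknown keys are rejected."""
    path = Path(path)
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    unknown = set(payload) - _SCALE_FIELDS
    if unknown:
        raise FormatError(f"{path}: unknown scale field(s) {sorted(unknown)}")
    missing = _SCALE_FIELDS - _SCALE_OPTIONAL - set(payload)
    if missing:
        raise FormatError(f"{path}: missing scale field(s) {sorted(missing)}")
    return ScaleDefinition(**payload)


def write_scale(scale: ScaleDefinition, path: PathLike) -> None:
    payload = {
        "test_type": scale.test_type,
        "cte": scale.cte,
        "fc_intercept": scale.fc_intercept,
        "fc_male": scale.fc_male,
        "fc_age": scale.fc_age,
        "fc_footsize": scale.fc_footsize,
        "adjusted_min": scale.adjusted_min,
        "adjusted_max": scale.adjusted_max,
        "smoothing": scale.smoothing,
        "log_base": scale.log_base,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# score reports

def report_to_dict(report: ScoreReport) -> dict:
    return {
        "participant": report.participant,
        "test_type": report.test_type,
        "input_quantity": report.input_quantity,
        "raw_score": report.raw_score,
        "fc": report.fc,
        "adjusted_score": report.adjusted_score,
        "final_score": report.final_score,
        "details": report.details,
    }


def write_score_reports_json(reports: Iterable[ScoreReport], path: PathLike) -> None:
    Path(path).write_text(
        json.dumps([report_to_dict(r) for r in reports], indent=2) + "\n",
        encoding="utf-8",
    )


def write_score_reports_csv(reports: Iterable[ScoreReport], path: PathLike) -> None:
    rows = [report_to_dict(r) for r in reports]
    for row in rows:
        row.pop("details")
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")
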