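"""From movement totals and YBT reaches to the final 1-10 balance score.

The scoring chain, given a :class:`~imep.types.ScaleDefinition`:

1. *raw score* — static tests invert the total movement, ``cte − total``
   (more sway = lower score, and the constant keeps cohort values positive);
   the YBT takes ``log(Σ of the six direction scores) − cte`` because reach
   scores live on a logarithmic scale and longer reaches mean *better*
   balance.
2. *adjusted score* — ``raw − 0.5·FC`` where FC is the demographic
   correction factor predicted from sex, age and foot size by a linear
   regression fitted on the derivation cohort; the 0.5 smooths its impact.
3. *final score* — min-max rescale of the adjusted score onto [1, 10] using
   the cohort's adjusted-score range, clamped so children outside the
   derivation cohort's extremes still receive a bounded score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from imep.types import (
    ParticipantProfile,
    ProtocolError,
    ScaleDefinition,
    ScoreReport,
    YBT_DIRECTIONS,
)


@dataclass
class YbtAttempt:
    """One YBT reach: direction, stance leg, distance and normalized score.

    ``normalized_score`` is reach/leg_length·10 — a dimensionless per-
    direction quantity comparable across children of different stature.
    """

    direction: str
    leg: str
    reach: float  # cm
    normalized_score: float

    def __post_init__(self) -> None:
        if self.direction not in YBT_DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.leg not in ("right", "left"):
            raise ValueError(f"leg must be right/left, got {self.leg!r}")
        if self.reach < 0:
            raise ValueError("reach must be non-negative")

    @classmethod
    def from_reach(cls, direction: str, leg: str, reach: float, leg_length: float) -> "YbtAttempt":
        if leg_length <= 0:
            raise ValueError("leg_length must be positive")
        return cls(direction, leg, reach, reach / leg_length * 10.0)


def ybt_composite(
    anterior: float,
    posteromedial: float,
    posterolateral: float,
    leg_length: float,
    leg_length_multiplier: float = 3.0,
) -> float:
    """Composite YBT score: (A + PM + PL) / (multiplier · leg length) · 10.

    The conventional composite divides the summed reach by three times the
    leg length; the multiplier is exposed for variant conventions.
    """
    if leg_length <= 0:
        raise ValueError("leg_length must be positive")
    if min(anterior, posteromedial, posterolateral) < 0:
        raise ValueError("reach distances must be non-negative")
    return (anterior + posteromedial + posterolateral) / (
        leg_length_multiplier * leg_length
    ) * 10.0


def raw_score_static(total_movement: float, cte: float) -> float:
    """Invert a static test's movement total: raw = cte − total.

    Negative raws are allowed (a child may move more than the derivation
    cohort's maximum); downstream clamping keeps the final score bounded.
    """
    if total_movement < 0:
        raise ValueError("total_movement must be non-negative")
    return cte - total_movement


def raw_score_ybt(
    direction_scores: Sequence[float], cte: float, log_base: str = "natural"
) -> float:
    """YBT raw score: log(Σ direction scores) − cte."""
    total = float(sum(direction_scores))
    if total <= 0:
        raise ValueError("sum of YBT direction scores must be positive")
    log_total = math.log(total) if log_base == "natural" else math.log10(total)
    return log_total - cte


def correction_factor(profile: ParticipantProfile, scale: ScaleDefinition) -> float:
    """FC = intercept + male·[sex==male] + age·Age + footsize·FootSize."""
    return (
        scale.fc_intercept
        + scale.fc_male * (1.0 if profile.is_male else 0.0)
        + scale.fc_age * profile.age
        + scale.fc_footsize * profile.foot_size
    )


def adjusted_score(raw: float, fc: float, smoothing: float = 0.5) -> float:
    """Subtract the smoothed correction factor: adjusted = raw − smoothing·FC."""
    return raw - smoothing * fc


def final_score(adjusted: float, scale: ScaleDefinition) -> float:
    """Min-max rescale of the adjusted score onto [1, 10], clamped.

    1 + 9·(adjusted − min)/(max − min); the cohort bounds map exactly to 1
    and 10 and anything beyond them clamps, so the instrument never reports
    outside its scale.
    """
    span = scale.adjusted_max - scale.adjusted_min
    score = 1.0 + 9.0 * (adjusted - scale.adjusted_min) / span
    return min(10.0, max(1.0, score))


def score_static_test(
    profile: ParticipantProfile, total_movement: float, scale: ScaleDefinition
) -> ScoreReport:
    """Score one static test (SLB or TBT) from its total movement in cm."""
    if scale.test_type not in ("SLB", "TBT"):
        raise ValueError(f"static scoring needs an SLB/TBT scale, got {scale.test_type}")
    raw = raw_score_static(total_movement, scale.cte)
    fc = correction_factor(profile, scale)
    adj = adjusted_score(raw, fc, scale.smoothing)
    return ScoreReport(
        participant=profile.nickname,
        test_type=scale.test_type,
        input_quantity=total_movement,
        raw_score=raw,
        fc=fc,
        adjusted_score=adj,
        final_score=final_score(adj, scale),
        details={"cte": scale.cte, "smoothing": scale.smoothing},
    )


def score_ybt_test(
    profile: ParticipantProfile,
    attempts: Sequence[YbtAttempt],
    scale: ScaleDefinition,
) -> ScoreReport:
    """Score the YBT from its six attempts (3 directions × 2 legs)."""
    if scale.test_type != "YBT":
        raise ValueError(f"YBT scoring needs a YBT scale, got {scale.test_type}")
    if len(attempts) != 6:
        raise ProtocolError(f"YBT requires 6 attempts, got {len(attempts)}")
    seen = {(a.direction, a.leg) for a in attempts}
    if len(seen) != 6:
        raise ProtocolError("YBT attempts must cover 3 directions x 2 legs exactly once")
    scores = [a.normalized_score for a in attempts]
    raw = raw_score_ybt(scores, scale.cte, scale.log_base)
    fc = correction_factor(profile, scale)
    adj = adjusted_score(raw, fc, scale.smoothing)
    return ScoreReport(
        participant=profile.nickname,
        test_type="YBT",
        input_quantity=float(sum(scores)),
        raw_score=raw,
        fc=fc,
        adjusted_score=adj,
        final_score=final_score(adj, scale),
        details={
            "cte": scale.cte,
            "log_base": scale.log_base,
            "per_direction": {
                f"{a.direction}_{a.leg}": a.normalized_score for a in attempts
            },
        },
    )


def score_participant(
    profile: ParticipantProfile,
    static_totals: Mapping[str, float],
    ybt_attempts: Sequence[YbtAttempt],
    scales: Mapping[str, ScaleDefinition],
) -> dict[str, ScoreReport]:
    """Score every test for one participant; pure function of its inputs.

    ``static_totals`` maps "SLB"/"TBT" to total movement in cm. Returns a
    report per test with every intermediate quantity recorded.
    """
    reports: dict[str, ScoreReport] = {}
    for test_type in ("SLB", "TBT"):
        if test_type not in static_totals:
            raise ProtocolError(f"missing {test_type} total movement for {profile.nickname}")
        reports[test_type] = score_static_test(
            profile, static_totals[test_type], scales[test_type]
        )
    reports["YBT"] = score_ybt_test(profile, ybt_attempts, scales["YBT"])
    return reports
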