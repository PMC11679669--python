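"""Re-derive a scoring scale from any cohort.

The procedure mirrors how the published constants were obtained:

1. pick the inversion constant ``cte`` from the cohort's range of total
   movement (smallest multiple of 50 strictly above the maximum, so every
   raw score is positive);
2. compute raw scores and regress them on sex, age and foot size to obtain
   the correction-factor (FC) coefficients;
3. apply the smoothed correction and record the cohort's adjusted-score
   range, rounded outward to integers — the bounds of the 1-10 rescale.

The YBT's cte does not follow the multiple-of-50 rule (its raw score is a
log), so for that test the constant is supplied explicitly (default 80).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from imep.scoring import YbtAttempt, raw_score_static, raw_score_ybt
from imep.types import ParticipantProfile, ScaleDefinition

DEFAULT_YBT_CTE = 80.0


@dataclass
class CorrectionFit:
    """OLS fit of raw scores on demographics: coefficients and their SEs."""

    intercept: float
    male: float
    age: float
    footsize: float
    se: dict[str, float]
    n: int

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.intercept, self.male, self.age, self.footsize)


def choose_cte(cohort_totals: Sequence[float], step: float = 50.0) -> float:
    """Smallest multiple of ``step`` strictly greater than the cohort maximum.

    Guarantees every raw score ``cte − total`` is strictly positive on the
    derivation cohort.
    """
    totals = np.asarray(list(cohort_totals), dtype=float)
    if totals.size == 0:
        raise ValueError("empty cohort")
    if (totals < 0).any():
        raise ValueError("totals must be non-negative")
    return float((math.floor(totals.max() / step) + 1) * step)


def fit_correction_model(
    raw_scores: Sequence[float], profiles: Sequence[ParticipantProfile]
) -> CorrectionFit:
    """OLS of raw score on (male indicator, age, foot size), unstandardized.

    Requires a cohort of at least 10 with variation in every predictor; a
    single-sex cohort (or constant age/foot size) makes the design rank
    deficient and is rejected naming the degenerate predictor.
    """
    if len(raw_scores) != len(profiles):
        raise ValueError("raw_scores and profiles must align")
    n = len(profiles)
    if n < 10:
        raise ValueError(f"need at least 10 participants to fit, got {n}")
    design = pd.DataFrame(
        {
            "male": [1.0 if p.is_male else 0.0 for p in profiles],
            "age": [p.age for p in profiles],
            "foot_size": [p.foot_size for p in profiles],
        }
    )
    for column in design.columns:
        if design[column].nunique() < 2:
            raise ValueError(f"degenerate predictor {column}: no variation in cohort")
    X = sm.add_constant(design)
    fit = sm.OLS(np.asarray(raw_scores, dtype=float), X).fit()
    params = fit.params
    bse = fit.bse
    return CorrectionFit(
        intercept=float(params["const"]),
        male=float(params["male"]),
        age=float(params["age"]),
        footsize=float(params["foot_size"]),
        se={
            "intercept": float(bse["const"]),
            "male": float(bse["male"]),
            "age": float(bse["age"]),
            "foot_size": float(bse["foot_size"]),
        },
        n=n,
    )


def adjusted_range(adjusted_scores: Sequence[float]) -> tuple[float, float]:
    """Cohort min/max of adjusted scores, rounded outward to integers."""
    scores = np.asarray(list(adjusted_scores), dtype=float)
    if scores.size == 0:
        raise ValueError("empty cohort")
    return float(math.floor(scores.min())), float(math.ceil(scores.max()))


def build_scale(
    profiles: Sequence[ParticipantProfile],
    test_type: str,
    static_totals: Optional[Sequence[float]] = None,
    ybt_attempts: Optional[Mapping[str, Sequence[YbtAttempt]]] = None,
    ybt_cte: float = DEFAULT_YBT_CTE,
    smoothing: float = 0.5,
    log_base: str = "natural",
) -> tuple[ScaleDefinition, CorrectionFit]:
    """Derive a complete ScaleDefinition from one cohort.

    For SLB/TBT pass ``static_totals`` aligned with ``profiles``; for YBT
    pass ``ybt_attempts`` keyed by nickname (six attempts each) plus an
    explicit ``ybt_cte``. Returns the scale together with the regression
    diagnostics. Before outward rounding of the range, the derivation
    cohort's own scores span exactly [1, 10].
    """
    if test_type in ("SLB", "TBT"):
        if static_totals is None or len(static_totals) != len(profiles):
            raise ValueError("static_totals must align with profiles")
        cte = choose_cte(static_totals)
        raws = [raw_score_static(t, cte) for t in static_totals]
    elif test_type == "YBT":
        if ybt_attempts is None:
            raise ValueError("ybt_attempts required for a YBT scale")
        cte = float(ybt_cte)
        raws = []
        for p in profiles:
            attempts = ybt_attempts[p.nickname]
            raws.append(
                raw_score_ybt([a.normalized_score for a in attempts], cte, log_base)
            )
    else:
        raise ValueError(f"unknown test_type {test_type!r}")

    fc_fit = fit_correction_model(raws, profiles)
    fcs = [
        fc_fit.intercept
        + fc_fit.male * (1.0 if p.is_male else 0.0)
        + fc_fit.age * p.age
        + fc_fit.footsize * p.foot_size
        for p in profiles
    ]
    adjusted = [r - smoothing * fc for r, fc in zip(raws, fcs)]
    lo, hi = adjusted_range(adjusted)
    scale = ScaleDefinition(
        test_type=test_type,
        cte=cte,
        fc_intercept=fc_fit.intercept,
        fc_male=fc_fit.male,
        fc_age=fc_fit.age,
        fc_footsize=fc_fit.footsize,
        adjusted_min=lo,
        adjusted_max=hi,
        smoothing=smoothing,
        log_base=log_base,
    )
    return scale, fc_fit
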