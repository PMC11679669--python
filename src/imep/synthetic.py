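"""Synthetic cohorts, sway trials, marker tracks and YBT reaches.

The generator emulates the statistical structure the instrument assumes, so
that every pipeline stage is testable with known ground truth:

* demographics drawn to match the derivation cohort (75 children aged 6-9,
  44 girls; age 7.27 ± 0.74 years, foot size 32.95 ± 2.14 EU, leg length
  67.45 ± 4.62 cm);
* quiet-standing sway as a mean-reverting (Ornstein-Uhlenbeck) 2-D COP
  process — the simplest stationary process with bounded excursions — with
  amplitude raised by eyes-closed testing and lowered with age, plate
  moments back-computed so the COP pipeline inverts the simulation exactly;
* marker excursions proportional to the COP excursion plus marker noise;
* per-direction YBT normalized scores with the observed ordering
  anterior > posteromedial > posterolateral.

Everything is reproducible from (config, seed). An optional ``fc_truth``
coefficient set makes movement totals depend on demographics through a known
linear model, for correction-factor recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.signal import lfilter
from scipy.stats import truncnorm

from imep import io_formats
from imep.scoring import YbtAttempt
from imep.types import MarkerTrack, ParticipantProfile, PlateTrial, SCORING_MARKERS

G = 9.81  # m/s²


@dataclass
class Demographics:
    """Population moments for profile draws (derivation-cohort values)."""

    age_mean: float = 7.27
    age_sd: float = 0.74
    age_bounds: tuple[float, float] = (6.0, 9.0)  # inclusion window
    foot_mean: float = 32.95
    foot_sd: float = 2.14
    leg_mean: float = 67.45
    leg_sd: float = 4.62
    height_mean: float = 1.28
    height_sd: float = 0.06
    weight_mean: float = 27.25
    weight_sd: float = 7.37
    female_proportion: float = 44.0 / 75.0
    right_dominant_proportion: float = 68.0 / 74.0


@dataclass
class SwayConfig:
    """Ornstein-Uhlenbeck sway parameters.

    ``base_amplitude_cm`` is the stationary SD of each COP axis for a
    reference-age child with eyes open on the SLB; the eyes-closed
    multiplier and per-year age slope scale it; ``tau_s`` is the
    mean-reversion time constant. ``marker_coupling`` maps COP position to
    marker position (markers high on the body travel farther than the COP),
    and ``marker_noise_frac`` adds marker-tracking noise proportional to the
    sway amplitude so that zero sway means zero recorded movement.
    """

    base_amplitude_cm: float = 1.0
    eyes_closed_multiplier: float = 1.5
    age_slope_per_year: float = -0.12  # older children sway less
    test_multipliers: dict = field(default_factory=lambda: {"SLB": 1.0, "TBT": 1.2, "YBT": 0.8})
    tau_s: float = 1.0
    marker_coupling: float = 4.0
    marker_noise_frac: float = 0.1
    fz_noise_frac: float = 0.01
    # must exceed twice the 50 Hz upper band edge of the cleaning filter
    sampling_rate: float = 250.0


@dataclass
class YbtConfig:
    """Per-direction normalized-score population means and dispersions.

    Means are the derivation cohort's estimated marginal means; the printed
    dispersions there are standard errors, so the per-attempt SD is a
    separate free parameter (default 2.0 score units).
    """

    anterior_mean: float = 18.57
    posteromedial_mean: float = 17.47
    posterolateral_mean: float = 16.30
    attempt_sd: float = 2.0


@dataclass
class FcTruth:
    """Known correction-model coefficients for parameter-recovery tests.

    When set, static totals are generated as
    ``cte_ref − (intercept + male·I[male] + age·Age + footsize·Foot) − ε``
    with ε ~ N(0, noise_sd), so the raw score under ``cte_ref`` follows the
    linear model exactly up to noise.
    """

    intercept: float = 1053.32
    male: float = 6.03
    age: float = -53.41
    footsize: float = -12.46
    cte_ref: float = 350.0
    noise_sd: float = 15.0


@dataclass
class GeneratorConfig:
    n: int = 75
    seed: int = 0
    demographics: Demographics = field(default_factory=Demographics)
    sway: SwayConfig = field(default_factory=SwayConfig)
    ybt: YbtConfig = field(default_factory=YbtConfig)
    fc_truth: Optional[FcTruth] = None

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be non-negative")
        if not 0.0 <= self.demographics.female_proportion <= 1.0:
            raise ValueError("female_proportion must lie in [0, 1]")


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  lo: float, hi: float, size: int) -> np.ndarray:
    if sd == 0:
        return np.full(size, mean)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(config: GeneratorConfig) -> list[ParticipantProfile]:
    """Draw ``config.n`` profiles; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    d = config.demographics
    n = config.n
    ages = _trunc_normal(rng, d.age_mean, d.age_sd, *d.age_bounds, size=n)
    feet = _trunc_normal(rng, d.foot_mean, d.foot_sd, d.foot_mean - 4 * d.foot_sd,
                         d.foot_mean + 4 * d.foot_sd, size=n)
    legs = _trunc_normal(rng, d.leg_mean, d.leg_sd, 1.0, np.inf, size=n)
    heights = _trunc_normal(rng, d.height_mean, d.height_sd, 0.5, np.inf, size=n)
    weights = _trunc_normal(rng, d.weight_mean, d.weight_sd, 10.0, np.inf, size=n)
    female = rng.random(n) < d.female_proportion
    right = rng.random(n) < d.right_dominant_proportion
    return [
        ParticipantProfile(
            nickname=f"sim{i:03d}",
            sex="female" if female[i] else "male",
            age=float(ages[i]),
            foot_size=float(feet[i]),
            leg_length=float(legs[i]),
            dominant_foot="right" if right[i] else "left",
            height=float(heights[i]),
            weight=float(weights[i]),
        )
        for i in range(n)
    ]


def sway_amplitude(profile: ParticipantProfile, test_type: str, eyes: str,
                   sway: SwayConfig, age_ref: float = 7.27) -> float:
    """Stationary COP SD (cm) for one trial's condition combination."""
    amp = sway.base_amplitude_cm * sway.test_multipliers.get(test_type, 1.0)
    if eyes == "closed":
        amp *= sway.eyes_closed_multiplier
    amp *= float(np.exp(sway.age_slope_per_year * (profile.age - age_ref)))
    return amp


def _ou_path(rng: np.random.Generator, n: int, dt: float, sd: float, tau: float) -> np.ndarray:
    """Exact discretization of a stationary OU process with SD ``sd``."""
    if sd == 0.0:
        return np.zeros(n)
    rho = np.exp(-dt / tau)
    innov_sd = sd * np.sqrt(1.0 - rho**2)
    impulse = np.empty(n)
    impulse[0] = rng.normal(0.0, sd)  # stationary start
    impulse[1:] = rng.normal(0.0, innov_sd, size=n - 1)
    # AR(1) recursion x[i] = rho·x[i-1] + shock as an IIR filter
    return lfilter([1.0], [1.0, -rho], impulse)


def generate_static_trial(
    profile: ParticipantProfile,
    test_type: str,
    eyes: str,
    seed: int,
    sway: Optional[SwayConfig] = None,
    support_foot: str = "right",
    ybt_direction: str = "n/a",
) -> tuple[PlateTrial, dict[str, MarkerTrack]]:
    """Simulate one trial: plate channels plus the three scoring markers.

    The COP is a 2-D OU path; Fz is the body weight with small noise, and
    the plate moments are back-computed from the simulated COP and the noisy
    Fz (Mx = y·Fz, My = −x·Fz with COP in metres), so running the COP
    pipeline on the trial recovers the simulated path to round-off.
    """
    sway = sway or SwayConfig()
    rng = np.random.default_rng(seed)
    duration = 5.0 if test_type == "YBT" else 16.0
    fs = sway.sampling_rate
    n = int(round(duration * fs))
    dt = 1.0 / fs
    amp = sway_amplitude(profile, test_type, eyes, sway)
    cop_x = _ou_path(rng, n, dt, amp, sway.tau_s)  # cm
    cop_y = _ou_path(rng, n, dt, amp, sway.tau_s)

    weight = profile.weight if profile.weight is not None else 27.25
    fz = weight * G * (1.0 + sway.fz_noise_frac * rng.standard_normal(n))
    fz = np.maximum(fz, 1.0)
    # shear forces: small fraction of body weight, same mean-reverting shape
    fx = 0.02 * weight * G * _ou_path(rng, n, dt, 1.0, sway.tau_s) if amp > 0 else np.zeros(n)
    fy = 0.02 * weight * G * _ou_path(rng, n, dt, 1.0, sway.tau_s) if amp > 0 else np.zeros(n)
    mx = (cop_y / 100.0) * fz
    my = -(cop_x / 100.0) * fz
    mz = np.zeros(n)
    trial = PlateTrial(
        participant=profile.nickname,
        test_type=test_type,
        eyes=eyes,
        support_foot=support_foot,
        ybt_direction=ybt_direction,
        sampling_rate=fs,
        fx=fx, fy=fy, fz=fz, mx=mx, my=my, mz=mz,
        nominal_duration=duration,
    )
    # markers ride the sway, amplified up the body, with tracking noise that
    # scales with the sway amplitude (zero sway -> zero recorded movement)
    tracks = {}
    noise_sd = sway.marker_noise_frac * amp
    for i, marker in enumerate(SCORING_MARKERS):
        coupling = sway.marker_coupling * (1.0 - 0.15 * i)  # higher landmarks move more
        tracks[marker] = MarkerTrack(
            marker=marker,
            x=coupling * cop_x + rng.normal(0.0, noise_sd, size=n),
            y=coupling * cop_y + rng.normal(0.0, noise_sd, size=n),
        )
    return trial, tracks


def generate_ybt_scores(
    profile: ParticipantProfile, seed: int, ybt: Optional[YbtConfig] = None
) -> list[YbtAttempt]:
    """Six YBT attempts (3 directions × 2 legs) with configured means.

    Normalized scores are drawn per direction; reaches are back-computed as
    ``score · leg_length / 10`` so the attempt record is self-consistent.
    """
    ybt = ybt or YbtConfig()
    rng = np.random.default_rng(seed)
    means = {
        "anterior": ybt.anterior_mean,
        "posteromedial": ybt.posteromedial_mean,
        "posterolateral": ybt.posterolateral_mean,
    }
    attempts = []
    for direction in ("anterior", "posteromedial", "posterolateral"):
        for leg in ("right", "left"):
            score = max(0.0, float(rng.normal(means[direction], ybt.attempt_sd)))
            attempts.append(
                YbtAttempt(
                    direction=direction,
                    leg=leg,
                    reach=score * profile.leg_length / 10.0,
                    normalized_score=score,
                )
            )
    return attempts


def generate_static_totals(
    profiles: Sequence[ParticipantProfile], truth: FcTruth, seed: int
) -> list[float]:
    """Movement totals whose raw scores follow a known demographic model.

    Under the reference constant ``truth.cte_ref`` the raw score of each
    participant equals the truth linear predictor plus Gaussian noise;
    totals are clipped at zero (clipping is rare under the default
    configuration). Used by correction-model recovery tests.
    """
    rng = np.random.default_rng(seed)
    totals = []
    for p in profiles:
        predictor = (
            truth.intercept
            + truth.male * (1.0 if p.is_male else 0.0)
            + truth.age * p.age
            + truth.footsize * p.foot_size
        )
        total = truth.cte_ref - predictor - rng.normal(0.0, truth.noise_sd)
        totals.append(max(0.0, float(total)))
    return totals


def _protocol_slots() -> list[dict]:
    """The 14 recorded attempts: slot id, test, eyes/direction, leg."""
    slots = []
    slot = 1
    for test in ("SLB", "TBT"):
        for eyes in ("open", "closed"):
            for leg in ("right", "left"):
                slots.append({"slot": slot, "test_type": test, "eyes": eyes,
                              "support_foot": leg, "ybt_direction": "n/a"})
                slot += 1
    for direction in ("anterior", "posteromedial", "posterolateral"):
        for leg in ("right", "left"):
            slots.append({"slot": slot, "test_type": "YBT", "eyes": "open",
                          "support_foot": leg, "ybt_direction": direction})
            slot += 1
    return slots


def generate_protocol(
    profile: ParticipantProfile, seed: int, sway: Optional[SwayConfig] = None
) -> list[tuple[dict, PlateTrial, dict[str, MarkerTrack]]]:
    """All 14 trials of one participant's session, deterministically."""
    out = []
    for meta in _protocol_slots():
        trial, tracks = generate_static_trial(
            profile,
            meta["test_type"],
            meta["eyes"] if meta["test_type"] != "YBT" else "n/a",
            seed=seed * 100 + meta["slot"],
            sway=sway,
            support_foot=meta["support_foot"],
            ybt_direction=meta["ybt_direction"],
        )
        out.append((meta, trial, tracks))
    return out


def emit_fixture_set(config: GeneratorConfig, out_dir) -> dict:
    """Write a complete fixture directory: plate TSVs, marker CSVs, cohort
    CSV, YBT attempt CSV and a ground-truth JSON of every parameter used.

    Returns a manifest of the files written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    profiles = generate_cohort(config)
    io_formats.write_cohort_table(profiles, out_dir / "cohort.csv")
    manifest = {"cohort": "cohort.csv", "plate_files": [], "marker_files": [],
                "ybt_files": []}
    for idx, profile in enumerate(profiles):
        pdir = out_dir / profile.nickname
        pdir.mkdir(exist_ok=True)
        for meta, trial, tracks in generate_protocol(profile, config.seed * 1000 + idx,
                                                     config.sway):
            stem = f"trial{meta['slot']:02d}_{meta['test_type']}"
            io_formats.write_plate_export(trial, pdir / f"{stem}.txt")
            manifest["plate_files"].append(f"{profile.nickname}/{stem}.txt")
            for marker, track in tracks.items():
                fname = f"{stem}_{marker}.csv"
                io_formats.write_marker_track(track, pdir / fname)
                manifest["marker_files"].append(f"{profile.nickname}/{fname}")
        attempts = generate_ybt_scores(profile, config.seed * 1000 + idx + 500_000,
                                       config.ybt)
        rows = "direction,leg,reach,normalized_score\n" + "\n".join(
            f"{a.direction},{a.leg},{a.reach!r},{a.normalized_score!r}"
            for a in attempts
        )
        (pdir / "ybt_attempts.csv").write_text(rows + "\n", encoding="utf-8")
        manifest["ybt_files"].append(f"{profile.nickname}/ybt_attempts.csv")
    truth = {
        "seed": config.seed,
        "n": config.n,
        "demographics": asdict(config.demographics),
        "sway": asdict(config.sway),
        "ybt": asdict(config.ybt),
        "fc_truth": asdict(config.fc_truth) if config.fc_truth else None,
    }
    (out_dir / "ground_truth.json").write_text(
        json.dumps(truth, indent=2, default=list) + "\n", encoding="utf-8"
    )
    manifest["ground_truth"] = "ground_truth.json"
    return manifest
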