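# imep

Balance scoring for primary-school children (6–9 years) on the IMEP 1–10
scale, from raw force-plate and marker-trajectory recordings.

Physical-education teachers have no practical access to laboratory
posturography, yet static and dynamic balance are central indicators of
perceptual–motor development at this age. The IMEP instrument closes that
gap: a child performs 14 recorded balance attempts — single-leg balance
(SLB, 16 s, eyes open/closed × both legs), tandem balance (TBT, same
structure) and the Y balance test (YBT, reaches in the anterior,
posteromedial and posterolateral directions with either stance leg) — and
body movement measured at three anatomical landmarks (acromion, umbilicus,
greater trochanter) is converted into a single score between 1 (greatest
imbalance) and 10 (greatest balance), adjusted for sex, age and foot size.

This package implements the full measurement chain as a tested library and
CLI:

* **io_formats** — plate exports (TSV), marker tracks (CSV), cohort tables
  (CSV), scale definitions (JSON), score reports (JSON/CSV);
* **plate_features** — 10–50 Hz zero-phase Butterworth cleaning, RMS,
  trial segmentation, centre-of-pressure (COP) path, 95% prediction-ellipse
  area, total force/moment;
* **marker_motion** — per-marker excursion, per-exercise movement, per-test
  total movement;
* **scoring** — raw → adjusted → final 1–10 score under a scale definition
  (the published scales ship with the package);
* **scale_builder** — re-derives a complete scale on any cohort;
* **synthetic** — cohort/sway/reach generator with known ground truth.

## The scoring model

For the static tests, the total movement `mvt` (cm, summed over three
markers and four exercises) is inverted with a test-specific constant, then
adjusted and rescaled:

    raw      = cte − mvt                         (cte: SLB 350, TBT 300)
    FC       = β₀ + β₁·[male] + β₂·age + β₃·foot_size
    adjusted = raw − 0.5·FC
    final    = 1 + 9·(adjusted − min)/(max − min),  clamped to [1, 10]

where (min, max) is the derivation cohort's adjusted-score range
(SLB: −72 to 230; TBT: −54 to 206). The YBT instead sums the six
leg-length-normalized reach scores and takes
`raw = ln(Σ scores) − 80`. The published FC coefficient sets for all three
tests are packaged as JSON resources.

## Worked example

```python
from imep import ParticipantProfile, published_scales, score_participant
from imep.scoring import YbtAttempt

girl = ParticipantProfile(nickname="ana", sex="female", age=7.23,
                          foot_size=32.48, leg_length=67.28)
attempts = [YbtAttempt.from_reach(d, leg, 17.0 * 67.28 / 10, 67.28)
            for d in ("anterior", "posteromedial", "posterolateral")
            for leg in ("right", "left")]
reports = score_participant(girl, {"SLB": 0.0, "TBT": 0.0}, attempts,
                            published_scales())
r = reports["SLB"]
print(r.raw_score, r.fc, r.adjusted_score, round(r.final_score, 3))
```

prints

```
350.0 262.4649 218.76755 9.665
```

A perfectly still child (zero total movement) earns the full raw score of
350; her demographic correction factor is 262.46, giving an adjusted score
of 218.77, which the SLB range (−72, 230) rescales to a final score of 9.67
— near-perfect, but short of 10 because the scale reserves its top end for
the adjusted maximum actually observed in the derivation cohort.

End-to-end from the shell:

```
imep simulate --n 2 --seed 5 --out fixtures/
imep movement fixtures/ --out movement.csv
imep score --cohort fixtures/cohort.csv --movement movement.csv \
           --ybt fixtures/ --out scores.json
```

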