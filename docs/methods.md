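# Methods

## The measurement chain

A scored session comprises 14 attempts: four single-leg-balance (SLB)
trials (eyes open/closed × right/left support), four tandem-balance (TBT)
trials with the same structure, and six Y-balance-test (YBT) reaches
(anterior, posteromedial, posterolateral × both stance legs). Static trials
last a nominal 16 s, YBT trials 5 s.

Two data streams are recorded per attempt: the force platform's six
channels (Fx, Fy, Fz in N; Mx, My, Mz in N·m) and video-digitized marker
trajectories (cm) at four landmarks — acromion, umbilicus, greater
trochanter, and L3. Only the first three landmarks enter the score; L3 is
read and reported but excluded, since scoring is defined on exactly the
three anterior/lateral markers.

### Plate signal processing

Channels are cleaned with a zero-phase (forward–backward) 4th-order
Butterworth bandpass of 10–50 Hz and summarized by RMS per channel over the
scored window. Static windows drop the first and last 3 s of the 16
(set-up transients and end-of-trial fatigue); YBT windows keep the initial
4 s containing the reach. Indexing is 0-based and half-open throughout.

The 10–50 Hz band removes DC, so the quantities that depend on the static
load are always computed from the **unfiltered** channels:

* COP: `cop_x = −My/Fz`, `cop_y = Mx/Fz` (m → cm), valid for a platform
  with its reference origin in the plate surface. Samples with
  Fz ≤ 20 N (unloaded plate) are dropped and counted.
* TF / MT: RMS over the window of the resultant magnitudes
  `√(Fx²+Fy²+Fz²)` and `√(Mx²+My²+Mz²)`.
* COP_A: the area of the 95% prediction ellipse,
  `π · χ²₂(0.95) · √det(Σ̂)` with Σ̂ the sample covariance of the COP
  cloud — the most common stabilometric dispersion summary. The quantile is
  configurable. A sway band of 10–50 Hz is unusual for posturography (sway
  energy is concentrated below ~2 Hz); keeping a filtered and an unfiltered
  stream side by side makes both interpretations available without guessing
  which the original processing intended.

Note that COP_A, TF and MT are computed and reported as trial covariates;
the mixed-model analyses that consume them in the source study are outside
this package's scope.

### Movement quantification

Per marker, the deviation along each image axis is the max−min excursion
over the scored window (the observable a human notes from a video
tracker; path length was rejected as frame-rate dependent), and the
marker's displacement is the hypotenuse `√(desplX² + desplY²)`. An
exercise's movement is the sum over the three scoring markers; a test's
total movement sums its exercises — 4 for SLB, 4 for TBT, 6 for YBT. (The
protocol's YBT records six positions even though the test-count notation
elsewhere speaks of four exercises per test; the six-slot reading is the
one consistent with the six-term YBT raw score and the 14-trial protocol.)

### Scoring

Static tests: `raw = cte − total_movement`, with cte the smallest multiple
of 50 strictly above the derivation cohort's maximum total (SLB 350, TBT
300), guaranteeing positive raws on that cohort. YBT:
`raw = ln(Σ of the six normalized reach scores) − 80`; each direction score
is `reach/leg_length·10`, and the composite convention divides the summed
reach by three times the leg length.

`adjusted = raw − 0.5·FC`, where FC is an ordinary-least-squares prediction
from the male indicator, age (years) and EU foot size, and the 0.5 halves
its impact. `final = 1 + 9·(adjusted − min)/(max − min)` clamped to
[1, 10]. The derivation write-up prints this rescale with "·9 − 1", which
maps the cohort onto [−1, 8] and contradicts its own stated 1–10 range; the
package implements the stated range. Clamping is deliberate: the instrument
must score children beyond the derivation cohort's extremes, and a bounded
scale is the only behaviour consistent with its published form.

Known inconsistency: with the published YBT constants, raw scores near
`ln(105) − 80 ≈ −75` cannot produce the published adjusted range of −175 to
526 under an FC of order 1. The package ships the printed constants
verbatim and documents, rather than resolves, the discrepancy; YBT final
scores under the published scale therefore cluster near the bottom of the
range and the log base (natural, configurable) is explicit.

## Scale re-derivation

`build_scale` repeats the derivation procedure on any cohort: choose cte
(multiple-of-50 rule for static tests; explicit for YBT, default 80, since
the published YBT constant does not follow the rule — the recorded maximum
was 84 yet cte is 80), fit the FC regression on raw scores with
unstandardized predictors, compute adjusted scores, and record the cohort
range rounded outward to integers (matching the printed integer bounds).
The regression requires n ≥ 10 and variation in every predictor; a
single-sex cohort is rejected naming the degenerate column. The fitted
intercept absorbs any difference between the chosen cte and the constant
used to generate the data; slope coefficients are invariant to it.

## Synthetic cohorts

The generator reproduces the statistical structure the instrument assumes,
with every parameter exposed:

* **Demographics** — truncated normal draws with the derivation cohort's
  moments: age 7.27 ± 0.74 years truncated to the 6–9 inclusion window,
  foot size 32.95 ± 2.14 EU, leg length 67.45 ± 4.62 cm, height
  1.28 ± 0.06 m, weight 27.25 ± 7.37 kg; sex Bernoulli with 44/75 female;
  right-foot dominance 68/74.
* **Sway** — the COP is a stationary 2-D Ornstein–Uhlenbeck process (exact
  AR(1) discretization), the simplest mean-reverting process giving bounded
  stationary sway. Base amplitude 1 cm (stationary SD per axis) with a
  1.5× eyes-closed multiplier, an exp(−0.12·(age − 7.27)) age factor
  (older children sway less), and per-test multipliers (SLB 1.0, TBT 1.2,
  YBT 0.8). Fz is body weight ± 1% noise; the plate moments are
  back-computed from the simulated COP and the noisy Fz, so the COP
  pipeline inverts the simulation to round-off. Marker positions ride the
  COP with a coupling of ~4 (landmarks high on the body travel farther),
  plus tracking noise proportional to the sway amplitude — so zero sway
  yields exactly zero recorded movement. Trials are generated at 250 Hz,
  comfortably above twice the cleaning filter's 50 Hz band edge.
* **YBT reaches** — normalized scores drawn per direction with means
  18.57 / 17.47 / 16.30 (anterior / posteromedial / posterolateral) and a
  per-attempt SD of 2.0 score units. The per-direction dispersions printed
  alongside the derivation cohort's means are standard errors of marginal
  means, not raw SDs, so the per-attempt SD is a declared free parameter
  chosen to give realistic between-attempt spread; reaches are
  back-computed as `score·leg_length/10`.
* **Known-truth totals** — for recovery tests, static totals can instead be
  generated from an explicit FC coefficient set plus Gaussian noise
  (SD 15 raw-score units), so the scale builder's regression can be checked
  against ground truth.

What the generator does **not** emulate: inverted-pendulum biomechanics,
learning or fatigue across trials, heteroscedastic marker noise, missing or
corrupted recordings, or any correlation between YBT reach and static sway
beyond demographics. Passing tests therefore demonstrate the pipeline's
correctness and the scale construction's statistical behaviour, not
validity of the instrument on real children.

## Numerical choices

* Zero-phase filtering (filtfilt) doubles the effective order and squares
  the passband gain; the passband tolerance tests allow for this.
* `choose_cte` uses floor(max/50)+1 multiples, so an exact multiple (e.g.
  300.0) steps up to the next one, keeping raws strictly positive.
* Outward integer rounding (floor/ceil) of the adjusted range means the
  derivation cohort's extreme members score within ~0.15 of 1 and 10
  rather than exactly at the bounds.
* Reported floats are written with `%.17g`, and plate/marker readers parse
  with round-trip precision, making writer/reader pairs bijective on valid
  documents.
* Default sampling rate when a plate export lacks one: 1000 Hz, typical
  for the platform class; always overridable, never inferred from data.

## Problem sizes

Test and acceptance runs use the derivation cohort's size (n = 75) for
calibration checks, n = 200 for coefficient recovery, 10⁵ points for the
ellipse-area and coverage checks, and 100 paired simulations for the
eyes-closed effect — sizes at which the Monte-Carlo tolerances stated in
the tests (3 standard errors) are meaningful.
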