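# Methods

This note documents the models, numerical choices and limitations of the
`itug` package in the order the pipeline applies them.

## Signal model and units

Recordings are uniformly sampled at 100 Hz: triaxial linear acceleration in
g (vertical V, mediolateral ML, anteroposterior AP; sensor range ±8 g) and
triaxial angular rate in °/s (yaw, pitch, roll; range ±250 °/s), from a
single IMU at the waist (L4–L5). Values outside the sensor range trigger a
validation warning, not a failure. Units stay on the acquisition scale
throughout; conversion to m/s² is an explicit helper (`acc_to_mps2`) and
never implicit, so smoothness outputs remain comparable across devices with
different gravity conventions.

"Angular acceleration" channels (Acc A) are obtained by central finite
differencing of the gyroscope rates (one-sided at the endpoints). The axis
naming follows the rotation axes: yaw rotates about the vertical axis (V),
pitch about the mediolateral axis (ML), roll about the anteroposterior axis
(AP). The "total" channel of either sensor is the per-sample Euclidean norm
of the three axes followed by mean subtraction, which removes the static
gravity magnitude from the accelerometer resultant.

## Preprocessing

* **Movement onset.** A channel is considered to contain movement from the
  first 10-frame moving window whose mean absolute deviation from the
  initial-noise baseline (mean of the first 100 frames) exceeds 3× the SD
  of those first 100 frames. The deviation is measured from the baseline
  mean rather than zero so a gravity offset cannot mask onset, and the SD
  is floored at 10⁻⁶ g to keep the rule defined for noiseless input. The
  onset index is the *start* of the first qualifying window, so it can
  precede the first supra-threshold sample by up to one window (0.1 s).
  Onset is detected once, on the resultant linear acceleration, and
  propagated to all channels.
* **DC and drift.** The mean is subtracted from every analysed segment
  (accelerometers pick up gravity, which otherwise dominates the spectrum).
  Drift removal defaults to linear detrending; a 1-s moving-mean subtraction
  is available (`drift_method="moving-mean"`). Note that the least-squares
  line through a finite sine has a small nonzero slope (~1/(2πfT) of the
  amplitude), so detrending preserves stationary oscillations only to a few
  percent at segment edges.

## Phase segmentation

Yaw and pitch angles are cumulative trapezoidal integrals of the gyro rates
starting at 0°. Integration applies **no** drift correction by default: the
integral of a sustained rotation is a genuine ramp, and detrending a yaw
trace with a net 360° course would corrupt both the rate baseline and the
net-angle test. An optional `drift_method` argument exists for long
recordings with appreciable gyro bias.

* **Turns** are runs where the smoothed (0.15 s moving average) |yaw rate|
  exceeds 30 °/s whose net angle change is ≥ 120°; exactly two are expected
  (the cone turn and the pre-sit turn; each ≈ 180°). With more than two
  candidates the two largest rotations are kept; with fewer, segmentation
  fails with a list of what was found.
* **Postural transitions** are the first and last excursions of the
  smoothed |pitch angle| with peak prominence ≥ 15°; each interval extends
  outward from its peak until the angle falls below 5% of the peak value.
* **Phases** (0-based, half-open intervals): sit-to-stand = onset → end of
  the first pitch excursion; walk 1 = → start of turn 1; turn = turn 1;
  walk 2 = → start of turn 2; the combined fifth phase spans turn 2 → end
  of stand-to-sit, matching the analysis convention of reporting "turn and
  stand to sit" as one phase (the internal turn-2/sit split is kept for
  diagnostics). Walk phases therefore include gait initiation/termination
  transients.

The default thresholds were chosen to recover the synthetic generator's
ground-truth boundaries (≤ 0.13 s worst-case error at default noise over 50
seeded trials, against tolerances of 0.2 s noiseless / 0.4 s noisy) and are
exposed in `SegmentationConfig` for tuning on real data, where ramp shapes
and turn styles vary more than the simulator's.

## SPARC

For a segment x, the pipeline (i) subtracts the mean, (ii) tiles the
segment end-to-end — ×4 for the five phases, ×2 for the full test — to
sharpen the dominant frequencies of short segments (tiling is distinct from
and applied before zero padding), (iii) computes a rectangular-window
periodogram zero-padded to 4× the next power of two, (iv) restricts it to
0–10 Hz, zeroes the DC bin and divides by the band maximum so
normPSD ∈ [0, 1] with max = 1, and (v) returns the negative discrete arc
length

SPARC = − Σᵢ √( (Δωᵢ / (f_high − f_low))² + (normPSDᵢ₊₁ − normPSDᵢ)² ).

Normalization is by the in-band maximum rather than the DC value: the DC
component is deliberately removed (gravity), so the classic V(0) reference
is unavailable, and max-normalization preserves the arc-length geometry
(flat unit spectrum ⇒ arc length exactly 1 ⇒ SPARC = −1, the upper bound).
Because the spectrum rises from the zeroed DC bin to a unit maximum, the
total variation of any computed profile is ≥ 1 and every computed SPARC is
≤ −1. Amplitude invariance is exact by construction. Each isolated unit
spectral peak adds ≈ 2 to the arc length, so a one-peak spectrum on a fine
grid scores ≈ −3, two peaks ≈ −5, and so on — the operational sense in
which "more dominant frequencies = less smooth".

Per-trial SPARC is computed for 8 channels × (5 phases + full test) = 48
values; the subject-level value is the arithmetic mean of the three trials.
SPARC magnitudes depend on segment length, tiling, padding and spectral
estimator; comparisons are meaningful within one configuration. (Published
full-TUG group means for this task differ between sources — e.g. −6.34/−4.23
vs ≈ −4.7/−3.2 for the same contrast — consistent with such configuration
sensitivity; this pipeline fixes one configuration, the tiled Table-2-style
one, and reports everything under it.)

## Freeze index (FR)

FR = (power in 3–8 Hz)² / (power in 0.5–3 Hz)², computed on the AP linear
acceleration over the full test (whether a per-phase FR is preferable is an
open choice; the full test was chosen for stability of the sub-Hz band).
Band power is the trapezoidal integral of the periodogram over the band;
the shared 3 Hz edge belongs to the locomotor band (bands [0.5, 3] and
(3, 8]). Interpretation anchors: ≈ 0 healthy, ≈ 0.3 parkinsonian without
freezing, ≈ 2 with freezing. FR is exactly scale invariant and requires
≥ 2 s of signal for band resolution; zero locomotor power is an error, not
infinity.

## Synthetic cohort generator

The generator is a test instrument, not a biomechanical model. It emulates
the features the analysis relies on:

* AP/V/ML acceleration as two harmonics (stride ≈ 2 Hz, step ≈ 4 Hz) under
  per-phase envelopes with raised-cosine ramps; braking/propulsion
  oscillation appears as the AP waveform. Vertical includes a +1 g gravity
  offset and sit-to-stand / stand-to-sit bursts.
* Spectral broadening (the parkinsonian "broad band of dominant
  frequencies") via slow frequency jitter (instantaneous frequency wanders
  by a relative bandwidth: 0.02 control, 0.06 + 0.20·severity PD) plus
  amplitude modulation — controlled, reproducible broadening rather than
  filtered noise.
* Freeze episodes as 3–8 Hz jittered-carrier bursts inside a phase that
  also locally suppress the locomotor harmonics in proportion to their
  intensity (a zero-intensity episode is bit-exactly a no-op).
* Yaw: two trapezoidal rate pulses integrating to ≈ 180° each (peak rate
  180/(duration − ramp), ramp 0.3 s, floored so the ±250 °/s range is
  respected); pitch: two 40° trapezoidal excursions ending exactly at the
  ground-truth boundaries; rhythmic trunk sway and, for PD, a ~5 Hz tremor
  on all gyro axes and (scaled by severity) on the acceleration axes.
* Per-subject phase durations drawn lognormally (CV 0.10) around nominals
  that sum to 9.15 s (control) and 14.04 s (PD) — the group-mean test
  durations the analysis is calibrated around; walking phases shrink 6% per
  trial around the trial-2 nominal (task learning strong enough to be
  detectable at the cohort's group sizes, as the study design assumes).
* A single severity parameter in [0.25, 1] (PD) drives broadening, tremor,
  amplitude loss, freeze-episode count/intensity and duration scaling;
  clinical scores (10 UPDRS III items, UPDRS III total, H&Y, FOG-Q, MMSE)
  are linear-plus-noise functions of severity clipped to instrument ranges,
  giving the correlation stage a known monotone ground truth (MMSE links
  negatively).

All randomness descends from one cohort seed via `numpy.random.SeedSequence`
spawning (cohort → subject → {parameters, scores, trials}); the
freeze-episode stream is split from the main noise stream. Default cohort:
31 PD + 6 controls × 3 trials = 111 recordings.

What the generator does **not** emulate: genuine biomechanics (joint
kinematics, double support), sensor artifacts (saturation, temperature
drift, quantization), postural sway nonstationarity, or realistic
inter-item UPDRS correlation structure. Passing tests therefore demonstrate
that the pipeline measures what it claims on signals with the assumed
spectral structure — not that the thresholds are clinically tuned.

## Statistics

* **Two-way ANOVA, Type II SS** by explicit nested-OLS model comparison:
  SS(A) = RSS(1+B) − RSS(1+A+B), symmetrically for B, and
  SS(AB) = RSS(1+A+B) − RSS(full); F uses the full-model residual mean
  square. Type II is used because the design is heavily unbalanced (31 vs
  6); on balanced designs it coincides with Type III (verified against
  statsmodels with sum-to-zero coding). Monte-Carlo calibration on 1,000
  null 31-vs-6 × 3 cohorts keeps the group-effect Type-I error at the
  nominal 5% ± 2%. Post-hoc: all pairwise cell t-tests, Sidak-adjusted with
  m = number of contrasts actually performed (logged in the result).
* **Sidak**: p_adj = 1 − (1 − p)^m, clipped to [0, 1].
* **Correlation map**: Pearson r, r² and two-sided p for every clinical
  score × phase × channel combination on trial-averaged SPARC, PD subjects
  only; raw p-values are reported (matching the published convention), with
  Sidak-adjusted columns available but off by default. Degenerate (constant)
  inputs yield NaN rows rather than aborting the map.
* **Effect sizes**: Cohen's d with pooled SD; classes small/moderate/large
  at 0.2/0.5/0.8 and a clinical-relevance flag at d > 0.4.
* **Power**: two-sample-t power via the noncentral t distribution
  (ncp = d·√(n₁n₂/(n₁+n₂)), df = n₁+n₂−2). The a-priori sample size for
  d = 1.57/0.79 ≈ 1.99 at α = 0.05 and 90% power is 6 per group under the
  **one-tailed** convention — the only convention that yields the published
  enrollment of 6; two-tailed gives 7. This tail choice is therefore the
  package default for `PowerSpec`. The correlation sample-size routine uses
  the Fisher-z approximation (n = ((z_α+z_power)/atanh r)² + 3), which for
  r = 0.65 at 95% power gives 22 one-tailed / 25 two-tailed; no standard
  convention reproduces a previously reported value of 20 for this setting,
  and the routine is provided as a generic tool only.

## Pipeline and reproducibility

`run_pipeline` takes one config (YAML/JSON or `PipelineConfig`) with
exactly one input source (a manifest of recordings, or a synthetic cohort
spec), runs segmentation → smoothness → statistics, and writes
`segmentation.tsv`, per-trial and per-subject `smoothness*.csv`,
`anova.csv`, `correlations.csv`, `effects.csv` and a `summary.json`
containing versions, the seed and a SHA-256 hash of the analysis-relevant
configuration (output paths and log level excluded). Identical configs
reproduce identical outputs bit-for-bit on synthetic input. Any stage
failure aborts with the stage name and offending recording id.

Problem sizes used by the shipped checks: 50 seeded trials for boundary
recovery, 1,000 null datasets for ANOVA calibration (at the statistical
layer — the responses are drawn directly on the 31/6 × 3 design, since the
IMU layer adds nothing to a Type-I-error question), and one full default
cohort (111 recordings) for the direction and dissociation checks.
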