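# Methods

## The outcome framework

`micropoint` operationalises an abnormal-points-only outcome for mesopic
microperimetry in intermediate AMD. The processing chain is:

1. **QC filter.** Exams with a false-positive catch-trial rate ≥ 33%
   (strictly: `rate < max_fp` is required, default `max_fp = 0.33`) are
   excluded and logged.
2. **Calibration.** A single global offset `c` (dB) is added to every
   measured threshold. It is either supplied or estimated from healthy
   controls as the mean over eyes of
   `expected(age) − (mean over that eye's exams of its grid mean)`.
   Per-eye aggregation before the cohort mean matches how cohort values
   are usually reported; for balanced designs (same number of exams per
   eye) linearity of the age model makes it identical to pooled-point
   aggregation, a property asserted in the tests. The offset is global,
   not per-eye: it corrects the device/normative mismatch, not
   individual eyes.
3. **Deviation scoring.** `deviation = (measured + c) − expected(age)`,
   with `expected(age) = 32.3 − 0.06·age` dB at every grid location and
   a pointwise SD of 1.78 dB. The model is deliberately
   location-independent; its documented validity covers the central 5°
   and is extended unchanged to the 7° ring of the study grid, an
   assumption inherited by everything downstream.
4. **Classification.** A point is abnormal under criterion `z` iff
   `deviation < −z·1.78` (strict inequality, mirroring "lower than").
   Defaults keep the cutoff unrounded (2.937 dB at z = 1.65, 3.56 dB at
   z = 2.0) because the unrounded value preserves the nominal tail
   probabilities: under the normative distribution the rounded 2.9 dB
   cutoff flags 5.2% of healthy points, violating the "less than 5%"
   definition. `rounded=True` reproduces the one-decimal clinical
   convention (2.9 / 3.6 dB).
5. **Summaries.** Per-eye: abnormal counts, whole-grid and
   abnormal-restricted means of thresholds and deviations, within-grid
   sample SD. Abnormal-restricted means are *undefined* (NaN, with
   `has_abnormal = False`) when an eye has no abnormal points; such eyes
   are excluded from restricted cohort aggregates (and counted) but kept
   in whole-grid aggregates and eligibility denominators. All "±"
   figures use the sample (n−1) SD. Percent-abnormal is reported under
   both defensible conventions — pooled (Σ abnormal / Σ points) and mean
   of per-eye fractions — since they differ on real cohorts and neither
   is canonical.
6. **Eligibility.** An eye qualifies for an abnormal-point endpoint when
   it has at least `min_abnormal` (default 5) abnormal points, either in
   any exam or in every exam (the strict enrolment reading).
7. **Agreement.** Bland–Altman statistics on exam1 − exam2 pairs:
   `mean_diff ± 1.96·sd_diff` limits. A single repeatability number is
   reported as the **span** (upper − lower = `2·1.96·sd_diff`); the
   half-width is also exposed because a lone printed "LoA" value is
   ambiguous between the two readings. Abnormal-point eye means are
   paired only for eyes with ≥ `min_abnormal` abnormal points in *both*
   exams. Cohen's d uses the equal-weight pooled SD
   `sqrt((sd_a² + sd_b²)/2)` by default (an n-weighted form is
   available); healthy "observations" are per-exam whole-grid mean
   deviations pooled across repeated exams (two exams per control eye
   count as two observations), with per-eye averaging available by
   pre-aggregating before the call.

## Grid conventions

Only the ring eccentricities of the two standard layouts are documented
(33 points at 0/1/3/5/7°; 61 points at 0–5°). The angular layout is this
package's convention: evenly spaced points per ring starting at 0° — 8
per ring for `study33` (1 + 4×8 = 33), 12 per ring for `norm61`
(1 + 5×12 = 61). Coordinates are abstract Cartesian degrees centred on
fixation; no nasal/temporal laterality semantics are attached, because
none of the analysis uses them. Custom layouts (name + eccentricity/angle
pairs) load from YAML.

## The synthetic cohort generator

The generator exists so that every stage can be exercised, and its
statistical behaviour verified, without clinical data. Each eye draws a
*true* sensitivity surface once, then produces `n_exams` (default 2)
measurements of it.

**Healthy eyes.** True surface = `expected(age) − device_offset`, flat
across the grid; ages Normal(62.2, 4.4) years. `device_offset`
(default 2.67 dB) is what the calibration stage should recover.
Measurement noise is additive Gaussian per point per exam,
`noise_sd_healthy = 1.73 dB`; since the true surface is flat, this is
also the healthy within-grid SD (≈ the 1.8 dB observed in controls) and
it makes a healthy pointwise Bland–Altman span of
`2·1.96·√2·1.73 ≈ 9.6 dB`.

**Diseased (iAMD) eyes.** Ages Normal(67.7, 7.1). Sensitivity loss has
two components:

- a **diffuse** whole-grid depression, Normal(−0.6, 0.5) dB clipped to
  ≤ 0, shared by all points of the eye;
- **focal** lesions on `k` points, `k = round(Normal(11, 8))` clipped to
  [0, 33], placed as a contiguous angular sector by default (drusen-like
  focal damage; random scatter is an option). Each affected point is
  depressed by Normal(m, 1.0) clipped to ≤ 0, where the eye's mean depth
  `m ~ Normal(−4.5, 1.2)` (clipped to ≤ −1 so "affected" is measurable).

The diffuse component is essential, not decorative: a pure
flat-plus-focal mixture with a third of points affected forces the
within-grid SD to be at least ~1.4× the whole-grid mean deviation,
whereas the disease profile being emulated has them nearly equal
(≈ 2.4 vs 2.3 dB). A diffuse shift moves the mean without adding
within-grid variance and resolves this. The defaults were
moment-matched analytically and confirmed by simulation: whole-grid mean
deviation ≈ −2.2 dB, mean within-grid SD ≈ 2.6 dB, mean abnormal-point
deviation ≈ −4.9 dB, with the abnormal count varying widely across eyes
(SD ≈ 7). Under these defaults the flagged fraction is ≈ 0.40 rather
than exactly one third — the price of the elevated unaffected-point
noise below, accepted as "roughly a third".

**Class-dependent measurement noise.** In diseased eyes the noise SD is
`noise_sd_unaffected = 2.05 dB` at unaffected points and
`noise_sd_lesion = 0.9 dB` at focally affected points. This asymmetry is
a deliberate calibration to the *reported agreement structure* of such
cohorts: with a single shared noise SD, the mean over the ~12 abnormal
points is necessarily noisier than the mean over all 33 points
(averaging fewer iid values), so abnormal-point eye means could never
repeat *better* than whole-grid means — yet that better repeatability is
precisely the empirical property the endpoint relies on. Solving the two
constraints jointly (pointwise Bland–Altman span ≈ 9.6 dB; abnormal-mean
LoA below all-points LoA) requires unaffected points to be roughly twice
as noisy as lesion points, which is what the defaults encode. This is a
phenomenological calibration, not a mechanistic claim about psychometric
slopes. An optional whole-exam session shift (`session_sd`, default 0)
can add correlated between-exam variation at the eye level.

**Mechanics.** Thresholds are truncated to the device range [0, 36] dB
and quantised to 0.1 dB (device output precision); ages to 0.1 years;
false-positive rates drawn Uniform(0, 0.2) and rounded to 4 decimals, so
CSV round trips are bit-exact. Truncation is rare under the defaults
(< 1% of points) and the generator warns when it is not, since floor
effects bias deviations. Each eye has its own RNG stream seeded from
(master seed, cohort, subject index), making datasets byte-reproducible
and independent of generation order. Ages can alternatively be drawn
uniformly (`age_uniform=(lo, hi)`) for null-calibration runs.

**What the generator does not emulate.** The device's 4-2 staircase and
its discrete threshold estimates; fixation instability and
false-negative behaviour; learning/fatigue order effects between the two
same-visit exams (beyond the optional session shift); spatial
correlation of noise; drusen biophysics; scotopic testing. Passing tests
therefore show the *pipeline arithmetic* is right under the assumed
data-generating process, not that real iAMD cohorts will reproduce any
particular value.

## Numerical conventions and edge cases

- Strict inequalities at every boundary that is stated as "less than":
  the QC ceiling and the abnormality cutoffs.
- Deviations are computed in full precision; only storage is quantised.
- Sample SD (ddof = 1) throughout; SD of a single value is reported as 0
  in eye summaries (constant grid) and rejected (n < 2) in Bland–Altman
  and Cohen's d, where it would be meaningless.
- Cohen's d raises on zero pooled SD rather than returning ±inf.
- Exams are validated, never repaired: out-of-range thresholds,
  incomplete grids and inconsistent exam-level fields are reported with
  file row numbers and abort the read.
- `run_pipeline` wraps stage failures with the stage name and writes a
  run log recording the package version, the offset actually applied and
  the criteria (z, cutoff, rounded or not) actually used.

## Problem sizes used in the checks

Simulation-based tests use 150–300 eyes per cohort (a few seconds each):
200 healthy eyes recover the 2.67 dB offset within ±0.1 dB (Monte-Carlo
SE ≈ 0.02 dB); 250 healthy eyes pin the flagged fractions to the normal
tails within binomial error; 300 diseased eyes make the agreement-span
ordering (abnormal-mean < whole-grid mean < pointwise) stable. The
acceptance script simulates 500 healthy eyes (16 500 points) for the
tail fractions. These sizes were chosen so that Monte-Carlo error is
well below the tolerances being checked.
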