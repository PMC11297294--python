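# Methods

This note documents the models and procedures implemented in `clingaze`,
the defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical conventions that matter for
reproducibility.

## Coordinate and time conventions

Gaze and ROI boxes live in normalized world-view coordinates: origin
top-left, x rightward, y downward, world-view = unit square.  This matches
the image-frame convention of scene-camera processing.  Gaze may legally
fall outside the unit square (off-world) and is preserved, never clipped;
only ROI box *areas* are clipped to the unit square when computing visual
real-estate.  Timestamps are milliseconds from session start; second-based
recordings convert at ingest (`time_unit="s"`).  At 120 Hz the nominal
sample period is 8.33 ms; per-sample dwell intervals are the gap to the next
sample capped at twice the nominal period, so recording dropouts do not
inflate gaze time.

## Event detection

**Fixations (I-DT).**  A fixation is when the eyes cease scanning and hold
the foveal field in one place.  The dispersion-threshold algorithm is used
because it is transparent and has two interpretable parameters; commercial
headset software rarely discloses its internals, so exact reproduction of
any particular vendor's event counts is a non-goal.  The contract: within
each maximal run of samples at confidence ≥ `min_confidence` (0.6), a
maximal window is a fixation iff its span ≥ `min_duration` (80 ms) and its
dispersion (x-range + y-range) ≤ `dispersion_threshold` (0.03).  Windows
grow greedily left to right; a sample that could either extend the current
fixation or start the next extends the current one (deterministic,
canonical I-DT).  The defaults permit the ~135 ms mean fixation durations
typical of natural-task mobile eye-tracking; all are config-exposed.  The
implementation is property-tested for exact equality against an exhaustive
O(n²) window search on random streams.

**Blinks.**  During a blink the pupil cameras lose the pupil, so confidence
collapses; blinks are maximal runs below `confidence_threshold` (0.5).  A
run spans from its first low sample to the next confident sample.  Runs
separated by gaps < `merge_gap` (20 ms) merge (flicker at blink edges);
durations outside [50, 500] ms are rejected — below as noise, above as
tracking signal loss, which is counted separately rather than silently
discarded.  Each blink carries the last confident gaze point before onset:
the eyes are closed during the blink, so the pre-blink locus is the standard
proxy for where attention was.

## ROI attribution and attention metrics

ROIs form a forest: here four clinical surfaces (patient mannequin, vital
signs monitor, paper ICU chart, AI display screen) with the AI
recommendation and four explanation panels (Q-value difference, predicted
mortality, feature importance, influential training examples) nested inside
the AI screen.  Boxes move (the wearer moves); lookups use zero-order hold
at the most recent frame.  Containment is half-open (`min ≤ v < max`) so
abutting panels partition the screen; a point in several visible ROIs goes
to the smallest-area one (area tie → lexicographically smallest id) plus all
its ancestors.  Points inside no ROI accrue to an implicit `elsewhere`
region so gaze proportions are well defined.

Per trial and ROI the pipeline reports gaze time, fixation count and mean
fixation duration (fixations attributed by centroid at the fixation's
temporal midpoint — robust to box motion within the fixation; a
majority-of-samples variant would be a straightforward extension and the
onset-time variant is available), blink rate, and the chance-gaze
correction.  Blink rate divides by the ROI's *own* gaze time, not trial
time: a per-trial denominator would penalize rarely-viewed ROIs and make
rates incomparable across surfaces with different dwell.  The chance
proportion is the time-weighted mean of the ROI's clipped box area over the
trial (zero while invisible); under spatially uniform gaze the
actual-to-chance ratio converges to 1 for every ROI, which is tested by
Monte Carlo with >10⁵ samples.

## Behaviour metrics

Weight-on-advice `I = (F − P)/(A − P)` is undefined when the advice equals
the prior estimate; the degenerate zone is `|A − P| ≤ ε` with ε = 1 ml/h for
fluid and 0.01 mcg/kg/min for vasopressor (one fine dose-step on each
scale).  Such trials are excluded from influence analyses and surface in QC
counts.  The headline value is winsorized to [0, 1] — the scale is defined
by its endpoints (ignore/adopt), and over- or under-shooting trials are real
but belong on the raw scale, which is always retained alongside.  Both
policies are configuration, not hidden assumptions.  Practice variation uses
the group mean *including* the prescriber's own dose (the group average is
the reference quantity); a leave-one-out variant is exposed.

## Statistics

Condition contrasts use the pooled-variance Student's t-test, two-sided,
with each group's 95% CI from its own SE and t critical value; Welch is an
option.  Correlation screens use Pearson's r (Spearman available).
Post-hoc power for the two-sided two-sample t-test uses the noncentral t
distribution with noncentrality `d·√(n₁n₂/(n₁+n₂))`, validated against a
10⁵-replicate simulation to ±0.01.  Whether group CIs should pool trials
across participants is genuinely ambiguous for repeated-measures designs, so
the report computes the trial-level pooling by default and offers a
participant-mean level (`participant_level=True`), labelled in the report
header.  No multiple-testing adjustment is applied anywhere; the report
footer says so.  Report generation is deterministic — it contains no RNG.

## Synthetic experiment generator

The generator emulates the study design end to end so every pipeline stage
can be tested against planted truth: 19 participants × 6 scenarios (4 safe,
2 unsafe AI advice; first trial always safe; unsafe scenarios in different
positions for different participants), 120 Hz gaze, trial durations
N(324 s, 72 s) floored at 60 s.

* **Attention.**  Each participant draws a Dirichlet profile over the nine
  leaf regions plus `elsewhere` (concentration 40 around the configured mean
  weights, AI-screen family mean 0.40); each trial perturbs it (concentration
  8).  Under the unsafe condition the mean AI-screen family weight is
  multiplied by `unsafe_ai_multiplier` (default ≈1.37) with the remaining
  weights renormalized, so the expected unsafe/safe AI-screen fixation-count
  ratio equals the multiplier exactly.
* **Gaze synthesis.**  Trials alternate fixations (ROI by the trial weights;
  target uniform in the ROI box with a 15% inset; duration lognormal, per-ROI
  means 135–160 ms, σ = 0.25, floored at 95 ms; 2·10⁻³ within-fixation
  tremor) and 30–80 ms saccades (linear sweeps).  Consecutive targets are at
  least 0.04 apart (L1): sub-threshold refixations of the same spot are not
  modelled, which keeps planted events identifiable.  Blinks follow
  fixations with probability `rate_ROI · dwell/60000` (per-ROI rates set to
  plausible surface-specific values, 6–20 bpm) as 100–300 ms confidence
  dips at the fixation locus.
* **Scene motion.**  All boxes share an AR(1) head-motion offset (step SD
  0.002, decay 0.97, clipped at ±0.035) sampled at 30 Hz, and the four
  explanation panels permute across the screen quadrants every trial — so
  hit-testing can never assume a static layout.
* **Prescribing.**  Baseline doses are N(reference, SD) floored at 0 with
  per-drug SDs (270 ml/h fluid, 0.05 mcg/kg/min vasopressor) chosen to give
  realistic practice-variation magnitudes; safe advice is 0.8–1.2× the
  scenario reference, unsafe advice an extreme over- (3.5×) or under-dose
  (0.1×) by scenario; `F = P + w(A − P) + noise` with w ~ Beta(2,3) safe /
  Beta(1.2,6) unsafe.  With noise SD 0 the pipeline recovers w exactly.
* **Ratings.**  Explanation usefulness ratings (0–4) are drawn per
  participant independently of gaze — planting zero rating–attention
  dependence by construction.

All randomness descends from one seed through spawned substreams
(participant- and trial-level), so runs are bit-reproducible.

**What the generator does not emulate** — and hence what passing tests do
not show about real recordings: calibration drift and parallax error,
systematic gaze bias near ROI edges, smooth pursuit, vestibulo-ocular
stabilization during walking, partial ROI occlusion and tag-detection
dropouts (boxes are always visible), pupil-size dynamics, and any
correlation between attention and prescribing behaviour (influence is
planted independently of the attention weights).  Results on real data
additionally depend on the vendor's gaze-estimation quality, which is out of
scope.

## Problem sizes in the test and reference runs

The test suite runs the fully realized pipeline on scaled experiments (2–4
participants, 8–40 s trials) where event-level behavior is identical to
full-length trials, and runs the full 19 × 6 design at the event-planning
level (planted per-trial counts without sample-level realization) for the
replicate-level statistical checks — 100 seeded replicates for the
safe-vs-unsafe detectability property.  This split keeps the chain covered:
sample-level recovery of planted events is verified once on realized
streams (recall and precision ≥ 0.95), and the statistical layer is
verified at the full design scale on planted counts.

## Known limitations

* I-DT dispersion is measured in normalized world-view units, not visual
  degrees; with a moving wearer the same threshold maps to different angular
  extents at different distances.
* Blink attribution to the pre-blink locus misassigns blinks that accompany
  gaze shifts.
* Trial-level condition contrasts pool repeated measures per participant
  (as does the participant-mean option, in the other direction); a
  mixed-effects treatment is deliberately out of scope.
* The `elsewhere` region has no chance-gaze baseline (it is the complement
  of a moving union of boxes), so its actual-to-chance ratio is reported as
  missing.
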