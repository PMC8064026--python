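# Methods

This note documents the analysis conventions, the synthetic-data model,
the numerical choices, and the known limitations of `handeye`.

## The analysis

### Signals and preprocessing

Three streams per lift trial, all starting at trial time zero:

| stream | content | units | rate |
| --- | --- | --- | --- |
| gaze | 2-D gaze position with per-sample validity | degrees of visual angle | 90 Hz |
| wrist / object | rigid-body position (x, y, vertical) | mm | 120 Hz |
| grip force | force orthogonal to the handle | N | 500 Hz |

Rigid-body positions are smoothed with a dual-pass (zero-phase) low-pass
Butterworth filter at 10 Hz and resampled to the common 90 Hz gaze grid
by linear interpolation; gaze is filtered at 30 Hz. The filter order is
2 per pass (4th-order effective) — the field-standard choice for
kinematics; the paper-trail conventions do not fix it, so it is exposed
in `PipelineConfig.filter_order`. Edge handling is reflective padding of
3 x order samples per pass; the dual pass squares the single-pass
magnitude response and cancels phase.

Velocity is the forward difference scaled by the sample rate, stamped at
interval midpoints; applying it twice gives acceleration. Speed is the
Euclidean norm of the velocity vector. Gaze gaps of at most 100 ms are
linearly interpolated before filtering but the filled samples stay
flagged invalid; longer gaps stay missing and split the series into
independently filtered segments.

### Event detection

* **Grasp onset** — first grip-force sample strictly above 1 N, rounded
  to the nearest 90 Hz frame when synchronising streams.
* **Reach onset** — first frame of the earliest run of >= 3 consecutive
  frames with hand speed strictly above 50 mm/s, searched strictly
  before grasp onset (this excludes the put-down movement at trial end,
  which the protocol does not otherwise mark).
* **Lift offset** — after the object first exceeds 50 mm/s following
  grasp onset, the first frame of the first run of >= 3 consecutive
  frames strictly below 50 mm/s.

Thresholds are strict; ties at exactly threshold never trigger, so
detection is deterministic on synthetic data. Reach metrics (movement
duration, peak hand speed, time-to-peak as % of movement time) are
computed on the reach window.

* **Saccades** — the scalar acceleration magnitude (norm of the per-axis
  second differences of the 30 Hz-filtered gaze) is thresholded at 5 x
  its median over the analysed segment; a saccade is a maximal run of
  >= 5 consecutive valid frames above threshold whose immediately
  adjacent frames are not missing. The threshold is computed per
  analysed phase (reach or lift), not per session: a segment's own
  background sets its scale, which also makes detection invariant to
  rescaling of the position signal. A small absolute floor of
  1 deg/s^2 — around three orders of magnitude below any saccadic
  transient but above filter-ringing residue — guards degenerate
  segments whose median acceleration is numerically zero.
* **Fixations** — dispersion-threshold identification (I-DT): grow a
  window from the 100 ms minimum; if the dispersion (x range + y range)
  is within 1 degree, extend greedily and emit the window with its
  centroid, else slide one frame. Windows may not span unfilled gaps;
  they may span short interpolated ones. I-DT runs on the
  gap-interpolated **unfiltered** positions: the zero-phase filter's
  step response rings by roughly 10% of the step amplitude on both
  sides of a saccade, which would consume most of the 1-degree
  dispersion budget of neighbouring windows and split fixations;
  raw-position I-DT is the textbook formulation. Event rates are
  onset-based: an event belongs to the phase containing its onset.
* **Gaze anchoring** — the onset of the last fixation beginning before
  grasp onset, relative to reach onset (negative when the final
  pre-contact fixation began before the reach).

### Hand-eye coupling

The vertical (gravity-aligned) wrist coordinate and the vertical gaze
coordinate are index-aligned at the grasp-onset frame and cropped to the
grasp-to-lift-offset segment. For every integer frame shift k in
[-K, K], Pearson's r is computed over the overlapping portion only,
each overlap independently standardised, so peak R stays in [-1, 1] and
reads as "how well the signals match once offset in time". Positive
lags mean the eye leads the hand. The peak maximises signed r (not
|r|); ties break toward the smallest |lag|, then positive. The unit
mismatch (mm vs degrees) is immaterial to Pearson correlation.

The default lag window is +-0.5 s, additionally constrained so every
overlap keeps at least max(10 frames, 50% of the segment): the segment
is short and unconstrained lags on tiny overlaps produce spurious
peaks. Trials whose segment is below the minimum overlap are invalid
for coupling but still contribute events and reach metrics. Trials with
negative peak r are retained. Per participant, peak R and lag are
aggregated as medians over trials; event rates and reach metrics as
means — following the per-metric aggregation conventions.

### Screening and group assignment

Quality codes 0-4 are consumed as data (they encode a manual video
review that is out of scope here): only codes 3-4 are analysable, and a
participant is excluded below 18 valid trials (50% of the 37-lift
protocol). MABC-2 percentiles assign groups: <= 5th percentile DCD,
> 15th Control, the half-open band (5, 15] Intermediate — kept for
correlational analyses, dropped from group tests.

### Inference

Each outcome is screened across the full included sample for values
beyond 3 SD of the mean (mean and sample SD on the original values);
each high outlier is replaced by 1.01 x the largest non-outlying score
and each low outlier by 0.99 x the smallest, in a single pass. Whether
the original analysis Winsorized per group or across the sample is not
recoverable; across-sample is the rule here. The multiplicative "1%
beyond" reading makes a replaced negative extreme move toward zero; the
outcomes in this analysis are effectively sign-homogeneous, so the case
is academic but documented.

Group tests are Student (pooled-variance) t tests with df = n1 + n2 - 2
and Cohen's d on the pooled SD — the pooled convention reproduces the
published demographic t and d values exactly, and the reported df = 56
identifies Student rather than Welch. A Shapiro-Wilk gate (p < .05 on
the pooled outcome) routes skewed outcomes to a Mann-Whitney U with the
rank-biserial correlation 1 - 2U/(n1 n2); the U p value is exact
(enumeration) when n1 x n2 <= 400 and tie-free, else tie-corrected
normal. Correlations are Pearson (or Spearman for gate-failing
outcomes) with a default stretched-beta (width 1) Bayes factor.

The two-sample Jeffreys-Zellner-Siow Bayes factor uses the default
zero-centred Cauchy prior with scale sqrt(2)/2 on the effect size,
computed by adaptive quadrature of the g-mixture representation
(relative tolerance 1e-8); BF10 < 1/3 is read as evidence for the null
and BF10 > 3 for the alternative. The implementation agrees with
pingouin's `bayesfactor_ttest` to machine-level precision and with a
dense log-grid trapezoid quadrature to 4+ significant figures (both are
cross-checks in the test suite, not the implementation).

One published value is not reproducible from printed summaries: the
DCD-Q group d of 1.7. Pooled-SD arithmetic on the printed means/SDs
gives d = 1.97 (and no standard SD convention gives 1.7); it was
presumably computed on Winsorized raw data. The t value (7.0)
reproduces exactly.

## The synthetic-data model

The generator produces trials whose *measured* quantities have known
ground truth, so every downstream estimator can be checked end to end.

* **Reach**: the wrist moves horizontally along a minimum-jerk profile
  whose rising 50 mm/s crossing is placed exactly at the configured
  reach onset given the configured peak speed (600 mm/s default — a
  brisk child-scale reach).
* **Lift**: object and wrist rise together by `lift_height` (150 mm
  default) along a minimum-jerk profile whose *falling* 50 mm/s
  crossing lands exactly at the configured lift offset (the profile
  duration is solved from `u*^3 (1-u*)^2 = 50 span / (30 H)`).
* **Grip force**: zero until grasp onset, then an exponential rise
  (tau = 20 ms) to a 6 N plateau, crossing 1 N within ~4 ms of the
  configured grasp onset.
* **Eye vertical**: the hand vertical profile rescaled at 0.1 deg/mm,
  advanced by `lag_true` (positive = eye leads), plus white Gaussian
  noise of `coupling_noise_sd`. White noise is the simplest model
  satisfying the pipeline's assumptions; autocorrelated noise is out of
  scope by default.
* **Eye horizontal**: piecewise-constant dwell positions with saccadic
  gaze shifts realised as single-frame steps (amplitude 7-9 deg) with a
  30% overshoot corrected on the next frame — a saccade with a
  glissade, completed within ~20 ms. This discrete shape is chosen so
  the 30 Hz-filtered acceleration magnitude stays above half its peak
  for 5-6 consecutive frames, satisfying the detector's run rule
  reliably down to vertical noise of ~0.1 deg; gentler shapes leave a
  mid-transient acceleration dip that splits or hides the run.
* **Event structure**: gaze is anchored (static) during the reach,
  pursues the rising object during the lift, and dwells with
  intermittent refixations during the hold. The total gaze-shift count
  is drawn as Poisson(`saccade_rate_true` x duration); static phases
  are filled at `fixation_rate_true` density first, the pursuit window
  takes the remainder as catch-up saccades, and overflow returns to
  spare static capacity. Shift starts keep >= 0.28 s separation so
  inter-shift dwells clear the 100 ms fixation minimum and filtered
  transients stay distinct. A deterministic *landing* catch-up saccade
  is placed 8 frames after the last pursuit window that still breaks
  the 1-degree dispersion threshold: pursuit deceleration otherwise
  passes through a band where minimum-duration dispersion windows
  flicker at threshold, which would make fixation counts ambiguous.
  Ground-truth fixations are the static-phase dwell windows (the hold
  dwell starts at the landing saccade).
* **Gaps**: missing-gaze runs start with per-frame probability
  `gaze_gap_prob` (default 0.01) and have geometric length (mean 2
  frames), exercising both the interpolation and the invalidation
  paths.
* **Measurement noise**: 0.15 mm on rigid-body markers and 0.01 N on
  force — order-of-magnitude realistic for optical capture and a
  laboratory transducer.

Cohorts draw per-participant traits from group-structured normals
matching the published demographic table, MABC-2 percentiles from the
group's band, and per-participant lags from a normal with SD 0.05 s
(trial-to-trial jitter 0.01 s). The published group comparison implies
a larger between-participant lag spread (~0.11 s); 0.05 s is chosen so
that a 0.1 s injected group difference is a large, reliably detectable
effect (d = 2) while the null calibration stays non-degenerate — the
spread of real children's lags is noisier than this generator assumes,
and statements about detectability transfer to real data only up to
that difference. Quality codes are drawn i.i.d. per trial
(default P(valid) = 0.75, giving ~28 of 37 valid trials). Every
participant and trial receives an independently derived seed from the
cohort seed, so any subset regenerates bit-identically.

### What the generator does not emulate

Pursuit gain below one, corrective-saccade coupling errors, blinks with
eyelid-droop artefacts, head movement, trial-to-trial adaptation,
object-size/mass effects, and autocorrelated tracker noise. Passing
tests therefore demonstrate that the estimators recover the quantities
they claim to measure under the stated signal model — not that the
model captures every property of children's gaze.

## Numerical choices

* Filter designs and steady-state initial conditions are cached; the
  dual pass is algebraically identical to
  `scipy.signal.filtfilt(padtype="even")` (asserted in tests).
* The cross-correlogram is computed with prefix sums and a single full
  correlation, O(n log n)-ish rather than per-lag slicing; overlap
  windows with zero variance yield NaN and are excluded from the peak.
  Peak ties (within 1e-12) break toward the smallest |lag|, then
  positive.
* Degenerate inputs are first-class: constant series reject correlation;
  all-invalid gaze segments raise; too-short filter inputs raise; a
  Shapiro-Wilk failure routes to the distribution-free test; quality
  screening errors on missing codes.
* Event times live on the 90 Hz grid; the grasp time found at 500 Hz is
  rounded to the nearest frame before synchronisation.

## Scaling of the simulation studies

The statistical-calibration study (type-I error and power of the group
test on median lag) runs 1,000 null and 200 effect cohorts at n = 19/39
with shortened 2.0 s trials, 4 trials per participant, all-valid
quality codes and a matching inclusion threshold; the full estimation
chain (generate, filter, resample, grasp/lift detection, synchronise,
cross-correlate, median, t/BF) runs for every trial. These sizes keep
the full study at a few minutes on one core while the binomial
uncertainty on the rejection rate stays below 0.7 percentage points.

A note on the Bayes-factor conventions at this design: with the default
prior and n = 19/39, BF10 crosses 1/3 at |t| = 0.65, and under a true
null P(|t_56| < 0.65) = 0.48 — so even a perfectly calibrated null
yields BF10 < 1/3 in slightly *under* half of cohorts; most
null-consistent t values leave BF10 between 1/3 and 1 ("inconclusive"
by the reporting convention). This is a property of the default prior
at these sample sizes, not of the pipeline.

## External validation path

The original study's trial-level data are deposited on OSF
(https://osf.io/fm247/). The published group results (peak R .38 vs
.39, lag .08 vs .05 s, lift-phase fixation rate 9.50 vs 10.67) are not
reproducible without that download; pointing `handeye run-all` at a
directory in the documented layout (after converting the deposit)
re-runs the full analysis and is the intended external check.

## Known limitations

* Irregularly sampled input is only supported through the linear
  interpolation path; no spline or Savitzky-Golay alternatives.
* No smooth-pursuit event class: pursuit frames are simply non-saccade,
  non-fixation.
* No frequency-domain coherence or time-resolved coupling.
* The saccade-threshold floor breaks exact scale invariance for
  pathological rescalings below ~1e-3.
* The MABC-2 percentile lookup is a copyrighted instrument; percentiles
  are inputs, never derived.
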