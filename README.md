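# handeye

Hand-eye coordination analysis of object-lifting trials in children,
with a synthetic-trial simulator for end-to-end validation.

When a person reaches for and lifts an object, gaze normally runs ahead
of the hand: the eyes anchor on the object before contact and lead the
hand's vertical trajectory during the lift. How tightly the two are
coupled — and by how much the eye leads — is a candidate index of
predictive (feed-forward) sensorimotor control, and has been proposed
as a marker for Developmental Coordination Disorder (DCD). This package
implements the full measurement chain for that question, for
researchers analysing simultaneous eye-tracking (90 Hz), motion-capture
(120 Hz) and grip-force (500 Hz) recordings of lift trials:

1. **Preprocessing** — dual-pass zero-phase Butterworth filtering
   (10 Hz kinematics, 30 Hz gaze), resampling to the common 90 Hz grid,
   finite-difference velocity/acceleration, gap interpolation.
2. **Kinematic events** — grasp onset (grip force > 1 N), reach onset
   (hand speed > 50 mm/s for 3 consecutive frames before grasp), lift
   offset (object speed < 50 mm/s for 3 frames after the lift), and
   reach metrics.
3. **Gaze events** — saccades (acceleration > 5 x the segment's median
   absolute acceleration for >= 5 valid frames) and fixations (I-DT:
   dispersion <= 1 degree for >= 100 ms), per-phase event rates, and
   gaze anchoring (onset of the final pre-contact fixation relative to
   reach onset).
4. **Coupling** — the vertical hand and eye signals are synchronised at
   the grasp-onset frame, cropped to the grasp-to-lift segment, and
   cross-correlated over integer frame shifts:

   `r(k) = corr( eye[0 : n-k], hand[k : n] )`, with each overlap
   independently standardised. The correlogram's maximum is **peak R**
   (coupling strength, in [-1, 1]) and its location the **hand-eye
   lag** (seconds; positive = eye leads hand). Trial values are
   aggregated per participant as medians.
5. **Screening and inference** — trial quality codes (0-4; only 3-4
   analysable), the >= 18-valid-trials inclusion rule, MABC-2
   percentile group assignment (<= 5th percentile DCD, > 15th Control),
   3-SD Winsorization, Student t tests with Cohen's d and
   Jeffreys-Zellner-Siow Bayes factors (default Cauchy prior, scale
   sqrt(2)/2), Shapiro-Wilk-gated Mann-Whitney U with rank-biserial
   correlation, and trait correlations with default-prior Bayes
   factors.

Because real recordings of children are noisy and scarce, the package
ships a first-class **synthetic-trial generator** with known ground
truth for every estimand: minimum-jerk reach and lift profiles whose
50 mm/s threshold crossings land exactly on the configured event times,
a step-like grip force, an eye vertical channel that is the hand
vertical advanced by a configurable lag plus configurable noise,
saccadic gaze shifts and fixation dwells at configurable rates, missing
gaze gaps, and group-structured cohorts (traits, percentile bands,
quality codes). Every estimator in the chain is validated against this
ground truth and against independent brute-force oracles.

## Worked example

```python
from handeye import TrialGenConfig, generate_trial, process_trial

rec, truth = generate_trial(TrialGenConfig(seed=1))   # one synthetic lift
res = process_trial(rec)                              # the full analysis
seg = res.segmentation
print(f"injected: reach {truth.reach_onset_true:.3f} s, grasp "
      f"{truth.grasp_onset_true:.3f} s, lift offset {truth.lift_offset_true:.3f} s, "
      f"lag {truth.lag_true:+.3f} s")
print(f"detected: reach {seg.reach_onset:.3f} s, grasp {seg.grasp_onset:.3f} s, "
      f"lift offset {seg.lift_offset:.3f} s")
print(res.coupling.summary())
```

prints

```
injected: reach 0.500 s, grasp 1.200 s, lift offset 2.200 s, lag +0.050 s
detected: reach 0.506 s, grasp 1.200 s, lift offset 2.206 s
Hand-eye coupling (cross-correlogram peak)
==========================================
peak R            0.9999
lag               0.0444 s (+4 frames at 90 Hz)
overlap at peak  87 frames
lags searched    [-0.500, 0.500] s
```

The detected events sit within a frame or two of the injected ones (the
3-consecutive-frame rule adds a small deterministic delay), and the
cross-correlogram recovers the injected 0.05 s lag at the nearest
90 Hz frame (4/90 = 0.044 s) with near-perfect peak R.
`res.coupling.plot()` draws the correlogram.

Cohort-level work uses the same pattern one level up: `generate_cohort`
builds a DCD/Control/Intermediate cohort, `run_cohort` turns it into a
per-participant outcome table, and `GroupStudy(...).fit()` returns a
results object whose `summary()` prints the group comparisons (test,
statistic, p, effect size, BF10) and trait correlations.

## Command line

```bash
handeye simulate --out cohort/ --seed 7          # write a synthetic cohort
handeye check    --in cohort/                    # validate the layout
handeye run-all  --in cohort/ --out results/     # the whole chain
handeye screen   --in cohort/ --out manifest.csv # participant manifest
handeye stats    --in manifest.csv --out stats.csv
```

Data live as plain comma-separated text, one directory per participant,
one file per stream with a header row and time in seconds (see
`handeye/io.py` for the column layout). There is no reader for native
eye-tracker or motion-capture session archives; converting a deposit
into this layout is the single extension point.

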