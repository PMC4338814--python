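# Methods

This note documents the models, algorithms and numerical choices behind
`sacmod`, in the order the pipeline applies them.

## Scientific setting

Saccadic latency (SL) — the delay between the onset of a peripheral target
and the onset of the gaze shift toward it, typically near 200 ms — is
modulated by cognitive demand: discriminating a fine feature of the target
(a Landolt-ring gap orientation) shortens latencies relative to a coarse
feature (color).  The package analyses this modulation in three groups —
patients with schizophrenia, their unaffected first-degree relatives, and
healthy controls — where the clinically interesting signature is that
patients show little modulation while relatives and controls show a large
one.  The per-subject summary is the saccadic latency difference

    SLD = mean SL(color) − mean SL(landolt),

positive when the higher-demand task shortens latencies.

## Synthetic cohorts (`oculosim`)

No public raw data exist for this paradigm, so the package ships a
simulator whose defaults are the study conditions: 13 patients, 24
controls, 10 relatives; 96 trials per subject in 3 blocks of 32 with task
(color / Landolt) and side (left / right) exactly balanced and randomly
ordered within each block; 200 Hz video-oculography; targets at 55°
eccentricity viewed from 80 cm.

**Trial timing.**  The paradigm is a step paradigm: fixation dot (500 ms),
first target at fixation (1000 ms), then the second target replaces it at
±55° with no gap.  The fixation and first-target durations are not
analysis-relevant (latency is measured from second-target onset) and are
configurable; the defaults are ordinary values for this kind of paradigm.

**Latency model.**  Each group has a bivariate distribution of latent
subject task means: means and between-subject SDs per task are the
published group statistics (patients 248±56 / 232±51 ms, controls 261±100
/ 193±27 ms, relatives 221±49 / 178±30 ms for color / Landolt).  A
subject's color and Landolt means are correlated; the correlation per
group (patients 0.88, controls 0.05, relatives 0.63) is calibrated so that
the implied SD of the within-subject task difference reproduces the
published within-group paired t statistics (t₁₂ = 2.19, t₂₃ = 3.26,
t₉ = 3.58).  Without this correlation the simulated paired contrasts would
be far noisier than the study's own, and group-level inferences would not
replicate.  Trial latencies are Gaussian around the subject mean
(within-subject SD 50 ms, a typical trial-to-trial latency spread),
truncated below at 80 ms by rejection sampling — the floor excludes
anticipatory saccades.  An ex-Gaussian trial distribution (exponential
tail τ, mean-preserving) is available as a config option, since empirical
latency distributions are right-skewed.

**Kinematics.**  Saccades follow the main sequence.  The velocity profile
is a raised cosine, v(t) = (2A/D)(1 − cos 2πt/D)/2 over duration D —
smooth, unimodal, and integrating exactly to the amplitude A.  Duration is
the larger of a linear law (2.2 ms/° · A + 21 ms) and the duration
2A/V(A) required for the profile peak to obey the saturating law
V(A) = 600 °/s · (1 − e^(−A/16°)).  The cap keeps peak velocity
physiological for large amplitudes (≈580 °/s at 55°, below the 750 °/s
artifact ceiling); for a 55° saccade the duration is ≈190 ms.  All four
constants are ordinary main-sequence values and are configurable.

**Noise.**  Gaussian position noise with SD 0.3° is added to every sample
of both channels, consistent with a tracker resolution of 0.5–1°.  The
simulator does not emulate head movement (the eye-tracker's gaze signal is
treated as a single channel), blinks (beyond optional velocity spikes for
testing artifact rejection), drift, or pupil-size artifacts.  Passing
tests therefore show that the algorithms are correct on signals with this
noise structure, not that they are robust to every artifact of real
recordings.

**Behavior.**  Button responses are simulated with per-group, per-task
accuracies near 95% and response-time means that encode the qualitative
published pattern (patients slower overall; Landolt slower for everyone,
disproportionately for patients).  These are qualitative artifact
defaults, not published values.

## Preprocessing (`preprocess`)

Order of operations, fixed and logged: visual-angle transform → artifact
masking → smoothing → velocity.

- **Visual angle**: angle = atan(offset / viewing distance), odd in the
  offset.
- **Artifact ceiling**: a velocity bound of 750 °/s is interpreted as a
  physiological-plausibility ceiling (it exceeds human saccadic peak
  velocities, and 750 °/s is a velocity, not a corner frequency); samples
  above it, plus 2 guard samples on each side, are masked and excluded
  from detection.  The mask is computed on the *raw* velocity, before
  smoothing, so spikes cannot leak into neighbours through the averaging
  window.
- **Smoothing**: 20 ms centered moving average of position (4 samples at
  200 Hz).  Edge windows shrink rather than trimming samples.  For the
  even 4-sample window the extra sample is taken on the future side; the
  half-sample lead this introduces offsets the half-sample lag of the
  detector's backward-extended onset, keeping latency estimates centred.
- **Velocity**: central differences of the smoothed horizontal position
  (one-sided at the ends).  Only the horizontal channel is used: targets
  lie on the horizontal meridian and latency is defined on horizontal
  gaze shifts.

## Saccade detection and latency (`saccades`)

Dual velocity threshold: events are seeded where speed ≥ 60 °/s and
extended to the nearest crossings of 15 °/s.  Concretely, every contiguous
run of samples ≥ 15 °/s containing a sample ≥ 60 °/s becomes a candidate;
its onset is the last sub-threshold sample before the run (ties broken
toward the earlier sample — conservative latency) and its offset the
first sub-threshold sample after it.  Candidates closer than 20 ms are
merged, events overlapping masked samples are dropped, and events shorter
than 10 ms or smaller than 1° are discarded (noise suppression at 200 Hz;
only the two velocity thresholds are study-specified, the rest are
ordinary detector hygiene and configurable).  A brute-force per-sample
scan is kept in the test suite as an independent oracle for the event
boundaries.

Latency is the onset of the first detected saccade after second-target
onset whose sign matches the target side and whose amplitude reaches 20%
of the target eccentricity.  The amplitude criterion is deliberately
permissive because large gaze shifts include head components the eye-only
amplitude omits.  Latencies outside [80, 1000] ms are invalid
(anticipatory / too slow), as are trials with no target-directed saccade;
every invalid trial carries a reason, and `qc_summary` reports the
per-subject partition.

Measured on simulated cohorts at the default settings, the detector
recovers ground-truth latencies with a mean absolute error of ≈2.6 ms
(maximum ≈5 ms, one sample) without noise and ≈5 ms with default noise.

## Group statistics (`stats`, `model`)

Per-subject task means use valid trials only.  The battery mirrors the
original analysis: paired t per group; Welch t (Welch–Satterthwaite df)
for between-group SLD contrasts; Levene's test (mean-centered by default,
median optional) for task-wise variance change; Wilcoxon signed-rank V
and rank-sum W in the R conventions (exact p where sample size and ties
permit, tie-corrected normal approximation otherwise); Pearson χ² without
continuity correction; a mixed-design ANOVA (between factor group, within
factor task; implemented via pingouin, with a sums-of-squares oracle in
the tests); Pearson correlation with t = r√((n−2)/(1−r²)); and paired-t
power from the noncentral t distribution with ncp = d√n (falling back to
the asymptotically exact normal approximation where the noncentral-t
tails underflow at large df).

Two conventions deserve note.  *Effect size*: the paired Cohen's d is the
mean difference divided by the RMS of the two condition SDs,
d = (m₁ − m₂)/√((s₁² + s₂²)/2) — this is the definition consistent with
all published group-level effect sizes here.  *Tails*: the between-group
SLD contrasts are directional hypotheses (patients modulate less), and
the published p-values for those Welch tests correspond to one-tailed
tests; the model computes both tails, reports both in every result, and
quotes the one-tailed value as the headline by default (`sld_tails=2`
flips this).  No multiple-testing correction is applied, matching the
original analysis.

`LatencyModulation` wraps the battery as a model object: built from a
trial-level latency table (plus optional behavioral table), `fit()`
returns a results object with the per-subject summaries, the group table
(means, SDs, SLD, percent reduction, d), every test keyed by name, a
plain-text `summary()` and JSON export.

## Classification (`classify`)

Subjects are classified from the two task means (SL Landolt, SL color).
Because the patient group has 13 members, every Monte Carlo iteration
draws a balanced subsample of 26 (13 per class, without replacement):
patients vs 13 of the 24 controls (`P_vs_C`); patients vs 13 of the 34
pooled controls+relatives (`P_vs_RC`); or 13 of the 23 pooled
patients+relatives vs 13 controls (`PR_vs_C`).  Within an iteration,
leave-one-out cross-validation trains a radial-kernel SVM (cost 1, kernel
width 1/n_features, features standardized with training-fold statistics —
the defaults of the standard SVM packages; standardization is
config-selectable) on 25 subjects and predicts the 26th.  Patients are
the positive class throughout, so sensitivity is the patient detection
rate.  Sensitivity, specificity and confusion counts are averaged per
iteration; mean counts are additionally rounded to integers for
reporting.  The full-scale configured default is 5×10⁶ iterations;
desk-scale runs use ~10⁴, and a running-mean convergence trace is
recorded because two-feature accuracy stabilises within a few thousand
iterations.  Everything is reproducible from (features, scheme,
iterations, seed).

## Problem sizes used in the shipped tests

The test suite chooses sizes that keep the whole run at a few minutes on
one core while leaving no property untested: ground-truth recovery uses
full 47-subject × 96-trial cohorts (noiseless and noisy); the
significance-pattern replication uses 100 replicate cohorts simulated at
the latency level (the trace-level detector is validated separately and
adds only ~one sample of quantisation); the classification
scheme-ordering comparison uses 20 replicate cohorts at 100 Monte Carlo
iterations per scheme; the exhaustive detector oracle runs on 200 random
traces up to 2000 samples; rank-test enumeration covers n ≤ 8.

## Known limitations

- The simulator's between/within variance split and within-subject SD are
  partly conventional: only group means, SDs and paired t statistics are
  published, which under-determines the full hierarchy.
- Eye–head coordination is not modelled; simulated "gaze" amplitudes equal
  the target eccentricity, so amplitude-dependent conclusions should not
  be read onto head-free recordings.
- The mean accuracy levels of the three classification schemes are
  data-dependent: synthetic cohorts reproduce their ordering in most
  replicates but not the published accuracy values themselves.
- Exact published test statistics (t, F, W, V, p on the original
  subjects) are not reproducible without the raw data; the package
  reproduces the procedures and every worked example derivable from the
  published group-level numbers.
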