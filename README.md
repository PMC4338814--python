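# sacmod

Saccadic-latency modulation analysis for video-oculography, built around a
schizophrenia state-marker paradigm.

Saccadic latency (SL) — the ~200 ms delay between the onset of a
peripheral target and the eye movement toward it — shortens under higher
cognitive demand.  In a peripheral recognition task with a low-demand
color condition and a high-demand Landolt-ring orientation condition,
healthy controls and first-degree relatives of patients with schizophrenia
show a 20–26% latency reduction in the demanding condition, while patients
show almost none.  The per-subject summary statistic is the saccadic
latency difference

    SLD = mean SL(color) − mean SL(landolt),

and the group analysis asks whether SLD is reduced in patients.

`sacmod` implements the complete analysis chain as a tested, reusable
package:

- **`sacmod.oculosim`** — synthetic cohorts of 200 Hz gaze traces with
  known ground truth: balanced 96-trial / 3-block designs, main-sequence
  saccade kinematics (raised-cosine velocity profiles), group latency
  distributions with between- and within-subject structure, tracker noise.
- **`sacmod.preprocess`** — visual-angle transform, 750 °/s artifact
  masking, 20 ms moving-average smoothing, central-difference velocity.
- **`sacmod.saccades`** — dual velocity-threshold detection (60 °/s onset,
  15 °/s offset), latency extraction with validity bounds and QC.
- **`sacmod.stats` / `sacmod.model`** — task means, SLD, percent
  reduction, paired and Welch t, RMS-pooled Cohen's d, Levene, Wilcoxon
  V/W, χ², mixed-design ANOVA (group × task), Pearson r, and paired-t
  power from the noncentral t distribution, wrapped in a
  `LatencyModulation` model whose `fit()` returns a results object with a
  `summary()` table and JSON export.
- **`sacmod.classify`** — Monte Carlo balanced-subsample (13 + 13)
  SVM-LOOCV classification of subjects from their two task means, with
  sensitivity/specificity/confusion reporting and three sampling schemes
  (patients vs controls, patients vs relatives+controls,
  patients+relatives vs controls).
- **`sacmod.cli`** — `sacmod simulate | detect | stats | classify | run |
  report` over plain-text trace/table files and YAML configs.

See `docs/methods.md` for the models, conventions and numerical choices.

## Worked example

Simulate a cohort at the study conditions (13 patients, 24 controls, 10
relatives, 96 trials each), fit the modulation model, and classify:

```python
from sacmod import CohortConfig, LatencyModulation, simulate_cohort
from sacmod.classify import SubsampledSVMClassifier

ds = simulate_cohort(CohortConfig(seed=1), include_traces=False)
results = LatencyModulation.from_cohort(ds).fit()
print(results.summary())

clf = SubsampledSVMClassifier.from_results(results, scheme="P_vs_RC",
                                           iterations=2000, seed=1)
print(clf.fit().summary())
```

prints (abridged):

```
Saccadic latency modulation
============================================================
group        n         color       landolt     SLD   red.%     d
patient     13     275+-73       260+-61        16     5.8   0.2
control     24     262+-82       194+-22        67    25.8   1.1
relative    10     211+-27       191+-25        20     9.5   0.8
------------------------------------------------------------
paired t patient                   stat=   2.06  df=12  p=0.06152
paired t control                   stat=   3.73  df=23  p=0.001107
paired t relative                  stat=   1.79  df=9   p=0.1068
welch sld patient vs control       stat=  -2.62  df=30.2  p=0.006768
...
scheme P_vs_RC: 2000 iterations, sensitivity 73%, specificity 91%,
accuracy 82% (TP 9, FP 1, TN 12, FN 4)
```

Reading the table: this simulated cohort reproduces the qualitative
finding — patients barely modulate (SLD 16 ms, d = 0.2) while controls
modulate strongly (SLD 67 ms, 26% reduction, d = 1.1), and patients'
SLD is significantly smaller than controls' (one-tailed Welch p = 0.007).
Individual cohorts vary: here the 10 relatives drew a small SLD (20 ms,
p = 0.11), illustrating the sampling noise at n = 10 that the replication
tests quantify.  The classifier separates patients from the pooled
comparison group well above chance on this draw; classification accuracy
is strongly cohort-dependent.

The same analysis runs end to end from the shell:

```sh
sacmod run --seed 1 --iterations 2000 --out results/
sacmod report --results results/
```

writing the latency table, QC counts, stats JSON, classification JSON and
a provenance log (config hash, seeds, versions) into `results/`.

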