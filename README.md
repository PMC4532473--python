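# emgcwt

Wavelet-based analysis of surface EMG from cyclic exercise: burst morphology,
median power frequency, and non-parametric fatigue statistics.

## What it does

During interval cycling, each pedal revolution produces one burst of muscle
activity. `emgcwt` turns raw single-channel surface EMG (plus a crank-switch
channel and MVC calibration recordings) into per-condition measures of muscular
effort and localized fatigue:

1. EMG is normalized to the mean RMS of three maximum voluntary contractions.
2. A complex Morlet continuous wavelet transform (ψ(t) = (1/√(bπ)) e^(−t²/b)
   e^(j2πf_c t), b = f_c = 1; f = f_s/s) gives a power map on a 5–500 Hz grid in
   1 Hz steps.
3. The first and last 10 pedal cycles of the interval are each re-mapped to
   0–100 % of cycle (401 columns, 2-D cubic interpolation) and averaged, giving one
   burst-dominated map per block.
4. Four-class Otsu thresholding isolates the highest-power region; its
   power-weighted centroid frequency, mean power, and pixel area quantify the
   burst. Integrating the map over time gives a power–frequency function whose
   median power frequency (MPF) is the classic fatigue index.
5. Work rate, main burst frequency, mean power, area, and MPF — as first-block
   values and as change scores (last − first) — are compared across intensity
   conditions (73/100/133 % of peak aerobic power) with Friedman's rank test
   (exact-permutation p for small n) and Dunn's post-hoc pairwise comparisons.

No recorded data ship with the package; a synthetic-EMG generator with exact
spectral and amplitude ground truth (see `docs/methods.md`) makes every stage
testable end to end, including full 7-subject parameter-recovery studies.

Intended users: exercise physiologists and biomedical-signal people who want a
reproducible, fully tested implementation of this pipeline, or a ground-truth
testbed for EMG time-frequency methods.

## Worked example

Simulate a 7-subject, 3-condition study in which only the supramaximal (133 %)
condition carries substantial within-interval fatigue, and analyze it:

```python
from emgcwt import StudySpec, run_synthetic_study, run_study_analysis

study = run_synthetic_study(StudySpec(n_subjects=7, seed=1))
result = run_study_analysis(study)
print(result.report())
```

Excerpt of the printed report (change-score arm):

```
  change | main_frequency_hz  Q = 11.1429 (df = 2), p = 0.001222 [exact]
         |   73 vs 100: z = 0.802, p = 1 (bonferroni)
         |   73 vs 133: z = 3.207, p = 0.004022 (bonferroni)
         |   100 vs 133: z = 2.405, p = 0.04847 (bonferroni)
  change | mpf_hz             Q = 14.0000 (df = 2), p = 2.143e-05 [exact]
         |   73 vs 100: z = 1.871, p = 0.1841 (bonferroni)
         |   73 vs 133: z = 3.742, p = 0.0005484 (bonferroni)
         |   100 vs 133: z = 1.871, p = 0.1841 (bonferroni)
```

Reading this: across the first interval the median power frequency declined and
the decline differed by condition (Friedman Q = 14 on 7 × 3 ranks, exact
p = 2.1 × 10⁻⁵ — every subject ranked the conditions identically); Dunn's test
locates the effect in the supramaximal-vs-lowest contrast (133 vs 73,
p = 5.5 × 10⁻⁴), exactly the injected ground truth (a 16 Hz MPF drop at 133 %
vs 0/4 Hz at 73/100 %). `result.features` holds the underlying per-subject table:

```
subject condition   block  work_rate  main_frequency_hz  mean_power  area_px    mpf_hz
    S01        73 first10      219.2          81.368953    0.118705     1118 85.160022
    S01       100 first10      300.0          81.385835    0.190976     2012 84.841116
    S01       133 first10      399.2          80.039777    0.317049     1297 84.167372
    S01       133  last10      399.2          65.674760    0.546660      724 69.974641
```

The same pipeline runs from the command line:

```bash
emgcwt simulate --seed 1 --n-subjects 7 --out data/      # delimited-text sessions
emgcwt analyze --config data/pipeline.yaml --out results/  # from files
emgcwt study --seed 1 --out results/                     # both steps in one
```

`analyze` accepts any sessions in the same text format (one `time<TAB>value` pair
per line for EMG and switch, three MVC files, per-session load), so recorded data
can be dropped in via the YAML config.

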