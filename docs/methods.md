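# Methods

## Overview

`emgcwt` quantifies muscular effort and localized fatigue from single-channel
surface EMG recorded during cyclic exercise (pedalling on a loaded ergometer with a
crank switch marking each revolution). The analysis chain is:

1. **Amplitude calibration.** Each session's EMG is divided by the mean RMS of that
   session's three maximum-voluntary-contraction (MVC) recordings, removing
   between-day differences in electrode placement and skin impedance. The whole MVC
   trial is used for the RMS (no plateau windowing).
2. **Cycle segmentation.** Pedal-cycle onsets are rising crossings of the switch
   channel's half-range threshold, debounced with a 50 ms window (≪ the 0.75 s cycle
   at 80 rpm). Cycles are half-open onset-to-onset intervals, so consecutive cycles
   partition time; `n` onsets delimit `n − 1` cycles. The first and last 10 cycles of
   the analyzed interval form the "fresh" and "fatigued" blocks.
3. **Time-frequency transform.** A continuous wavelet transform with the complex
   Morlet mother wavelet

   ψ(t) = (1/√(bπ)) · exp(−t²/b) · exp(j2πf_c t),  b = f_c = 1,

   evaluated on a linear 5–500 Hz grid in 1 Hz steps (496 rows) using the
   scale–frequency relation f = f_c·f_s/s. Power is the squared coefficient
   magnitude. The transform is synthesized in the frequency domain (the Morlet
   Fourier transform is the Gaussian exp(−π²b(ν − f_c)²)), one FFT for the signal
   plus one Gaussian multiply and inverse FFT per scale.
4. **Percent-cycle maps.** Each cycle's scalogram columns are re-mapped onto a fixed
   0–100 % axis with 401 columns (0.25 % steps, both endpoints included) by cubic
   spline interpolation per frequency row (equivalent to bicubic interpolation on
   the lattice, since the frequency axis is untouched; both routes are implemented
   and cross-checked). Negative cubic overshoot is clipped at zero. The block's 10
   maps are averaged elementwise.
5. **Burst morphology.** The averaged map's pixel values are partitioned into four
   classes by multi-level Otsu thresholding of the linear 256-bin histogram over
   [0, max]; the top class isolates the activation burst and suppresses low-power
   artifacts. 4-connected components of the top-class mask are candidate bursts; the
   maximum-area component (maximum-mean-power is available and agrees on well-formed
   maps) yields three features: the power-weighted centroid frequency ("main burst
   frequency", Hz), the mean power over the region, and the area in map pixels.
6. **Median power frequency (MPF).** The map is integrated over the percent axis
   (trapezoid) to a power-vs-frequency function; the MPF is where cumulative power
   (trapezoid over frequency) first reaches half the total, with linear
   interpolation between grid points to remove the 1 Hz quantization.
7. **Statistics.** For each dependent variable (work rate = cadence × load, main
   burst frequency, mean power, area, MPF), two repeated-measures arms are analyzed
   across the three intensity conditions (73/100/133 % of peak aerobic power):
   first-block values, and change scores (last block − first block). Each arm uses
   the Friedman rank test (within-subject mid-ranks, standard tie correction;
   exact-permutation p by full enumeration of the (k!)^n rank assignments when that
   is small, e.g. (3!)⁷ = 279 936 at n = 7, otherwise the χ² approximation with
   df = k − 1) followed by Dunn's pairwise comparisons,
   z = |R̄_a − R̄_b| / √(k(k+1)/(6n)), reported both Bonferroni-adjusted (default)
   and unadjusted ("LSD" mode); the mode used is recorded in every output row.

## Wavelet normalization

Two per-scale daughter normalizations are implemented. **L1** (default), daughter
(1/s)ψ(t/s): a unit sinusoid produces the same peak power at every scale, so the
row-argmax of the power map sits on the tone's frequency — the property that
cross-frequency power comparisons implicitly assume, and the convention of MATLAB's
`cwt`. **L2**, unit-energy daughters: preserves energy but biases a tone's row-argmax
low by ≈ f/(4π²) (≈ −2.5 %), which is unacceptable for frequency readouts on this
grid. The normalization used is recorded in the scalogram metadata.

At b = 1 the Morlet row response to a tone at f₀ is exp(−2π²(f₀/f − 1)²): a relative
bandwidth of ~16 % with a high-frequency skew (symmetric in 1/f, not in f). Two
consequences worth knowing:

* **The map-level MPF of a narrowband signal is biased upward** — about +4.6 Hz for
  a pure 80 Hz tone and +7 to +9 Hz for realistic 40 Hz-wide bursts at 60–120 Hz
  (verified against a closed-form convolution of the source spectrum with the row
  response). This is a property of the low-Q kernel, not of the MPF estimator;
  **change scores cancel it** almost exactly, and changes are what the fatigue
  analysis rests on. Absolute MPF values from this pipeline should not be compared
  against narrowband spectral analyses without accounting for the kernel.
* Edge effects are handled by zero-padding; the per-row cone-of-influence half-width
  (the envelope e-folding time, √b·s/f_s) is stored on every scalogram. Cycle
  extraction does not exclude edge-affected columns by default (the analysis blocks
  are interior spans with a 0.5 s raw-signal margin on each side where available),
  but `Scalogram.interior_columns()` exposes the conservative interior slice for
  diagnostics and validation.

## Synthetic data generator

The generator emulates the study conditions with exact ground truth: 60 s intervals
of 80 cycles at 80 rpm sampled at 2048 Hz; one burst per cycle occupying 40 % of the
cycle; burst spectra Gaussian in amplitude, centred on the target median frequency
with `spectral_bandwidth_hz = 40` (twice the amplitude-response SD); burst RMS a
condition-dependent fraction of MVC; a white baseline floor (RMS 0.02 × MVC) between
bursts so the Otsu background class is realistically populated; a 10 ms switch pulse
at each cycle onset; three MVC recordings rescaled to exact target RMS.

Bursts are built by inverse FFT of the deterministic amplitude spectrum with
uniformly random phases, then enveloped with a Tukey (α = 0.25) window to avoid
rectangular-gating splatter. Because windowing random-phase noise perturbs the
amplitude spectrum (±2 Hz SD jitter of the realized median frequency), each burst is
refined with 8 alternating projections — re-impose the target amplitude spectrum,
re-apply the envelope — bringing the worst-case per-burst median-frequency error
under 1 Hz; the burst is finally rescaled to its exact target RMS. Fatigue is a
linear cycle-by-cycle drift of the median frequency (downward) and burst RMS
(upward); the per-cycle truth table stores both trajectories exactly.

The default three-condition study mirrors the qualitative pattern of interval-
cycling EMG: amplitude and ergometer load graded with intensity (burst RMS
0.45/0.60/0.80 × MVC, load 2.74/3.75/4.99 giving 219/300/399 W-equivalent at
80 rpm), and within-interval fatigue graded but substantial only at the supramaximal
intensity (MPF drop 0/4/16 Hz, burst-RMS rise ×1.0/×1.1/×1.3). Between-subject
random effects: a Gaussian MPF offset (SD 5 Hz) and a log-normal amplitude factor
(SD 0.10). All randomness fans out deterministically from one study seed.

What the generator does **not** emulate: motor-unit action-potential trains and
recruitment/derecruitment dynamics, electrode crosstalk, movement artifacts, cadence
variability (cycles are exactly equal length, so the work-rate change score is
degenerate at zero), and condition-dependent burst *shape* (duty and bandwidth are
shared across conditions, so the burst-area feature carries no designed effect).
Passing tests therefore demonstrate correct recovery of spectral and amplitude
ground truth under clean cyclic structure, not robustness to real-world artifacts.

Note that with a linear within-interval drift, the first 10 cycles of a fatiguing
condition already contain a small decline (≈ 0.9 Hz of a 16 Hz drop), so the
"fresh-state" arm is not an exact null for MPF in the synthetic study — rank tests
at n = 7 can detect even this sub-Hz but consistent ordering.

## Numerical choices

* Otsu thresholds are found by an exact dynamic program over histogram-bin
  boundaries (O(classes · bins²)), equivalent to exhaustive search; ties break
  toward the lowest thresholds. Degenerate inputs (constant maps, fewer distinct
  values than classes) raise. An empty top class raises by default
  (`fallback_to_next_class` merges the top two classes instead).
* Burst selection ties break by the secondary criterion, then by the lower centroid
  frequency, making the choice deterministic.
* The top Otsu threshold scales with the histogram range [0, map max], i.e. with the
  single hottest pixel; on smooth unimodal maps this makes the top-class area (and
  hence mean power) the noisiest features — an intrinsic property of
  histogram-range-anchored Otsu worth remembering when powering studies on these
  features.
* Cycle-block scalograms in the pipeline are computed in single precision
  (complex64), which halves time and memory at ~1e-6 relative accuracy; the
  standalone `scalogram()` defaults to double precision.
* When all cycles in a block have equal length (constant cadence), segments are
  averaged before one remap instead of remapped individually (interpolation is
  linear in the data; the two orders agree to the sub-1e-6 zero-clip of cubic
  overshoot). Unequal-length cycles take the per-cycle path.
* Exact Friedman enumeration is limited to designs with ≤ 2 × 10⁶ rank assignments;
  larger designs use the χ² approximation (`method="chisq"`).
* CSV outputs are written with a fixed float format, so a fixed seed reproduces
  byte-identical feature and statistics tables.

## Interfaces

Sessions are delimited text (time, value) with CSV truth sidecars and flat key-value
configs; scalograms and cycle maps persist as `.npy` arrays with JSON headers, so
every stage can be re-run from saved intermediates. The CLI wraps the library in
three composite commands (`simulate`, `analyze`, `study`); per-stage operations are
the library functions themselves. Output directories are versioned (`out`, `out-1`,
…) rather than overwritten.

## Known limitations

* Absolute MPF carries the kernel smearing bias described above (use change scores
  or a higher-Q wavelet — not provided here — for absolute readouts).
* Burst area and mean power inherit segmentation variance from the extreme-value
  anchoring of the Otsu histogram range.
* Only complete-block designs are supported in the statistics (no missing cells).
* The "first interval" of a multi-interval session must be identified by metadata
  (interval boundaries in the config); no automatic interval detection is provided.
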