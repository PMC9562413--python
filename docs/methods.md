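# Methods

This note documents the models, algorithms, and numerical choices behind the
package: what is computed, under which assumptions, and where the design was
genuinely open.

## Signal model and preprocessing

Records are two simultaneous channels sampled at a common rate (default
1 kHz): a phonocardiogram (PCG) and a ballistocardiogram (BCG), with one
cuff SBP label per record. Each channel is normalized to unit peak
magnitude (max-abs) once, **before** filtering. Normalization is not
repeated after filtering: rescaling a filtered record to its own maximum
would blow beat-free noise up to full amplitude and defeat the detectors'
prominence thresholds, which are expressed relative to the raw record's
peak.

Band-pass filters:

* **PCG, 34–50 Hz**, Blackman-window FIR. The kernel is symmetric
  (type-I linear phase), so single-pass convolution with `mode='same'` is
  exactly zero phase. Default **501 taps**: long enough for the Blackman
  stopband (≈ −74 dB; |H(10 Hz)| ~ 1e-5, |H(120 Hz)| ~ 1e-6) while keeping
  the kernel's transition-band ringing to ~90 ms. This length matters:
  kernels of ~1000 taps ring for ~180 ms, which spans the diastolic gap at
  elevated heart rates and measurably (2–3 ms) drags the envelope peak of
  one heart sound toward its neighbor.
* **BCG, 1–10 Hz**, order-2 Butterworth applied forward–backward
  (`sosfiltfilt`), hence zero phase with |H|² magnitude. An FIR realization
  is also provided (needs ≥ ~4000 taps for DC rejection at a 1 Hz edge).
  The IIR default is deliberate: a sharp FIR edge at 10 Hz reshapes any
  I–J–K complex whose peak-to-trough spacing (45–55 ms) approaches the
  band-edge half period, dragging the flanking minima by 12–20 ms. The
  gentle Butterworth roll-off keeps those extrema within ~1 ms.

Zero-phase application everywhere is essential: every downstream feature is
a timing difference between two differently filtered channels, so any
uncompensated group delay would bias every interval.

## Event detection

Detection is anchored on the BCG J wave:

1. **J**: local maxima above a prominence threshold (default 0.1 of the
   record's normalized scale) with a refractory spacing between successive
   peaks (default 0.4 s, i.e. up to 150 bpm; conflicts keep the larger
   peak). A literal reading of the source procedure would place the next
   search 4 ms after the previous J — physiologically impossible as a beat
   spacing (> 240 bpm by far); we treat it as a refractory interval of
   ~0.4 s, exposed as `min_jj_s`.
2. **I, K**: the nearest local minima before/after each J within ±150 ms
   (configurable); triplets missing either are marked incomplete.
3. **S1, S2**: heart sounds are oscillatory bursts, so a raw-sample maximum
   is ambiguous; the search runs on a rectified, zero-phase low-passed
   (default 20 Hz, order-4 Butterworth) PCG amplitude envelope. S1 is the
   largest envelope local maximum in `[t_J − 0.3 s, t_J)`; S2 the largest
   in `t_K ± 0.15 s`. Windows crossing the record boundary mark the cycle
   incomplete rather than raising. Ties break toward the earlier time, so
   output is deterministic.

Cycles missing any of the five events are kept with a `complete=False`
flag; only complete cycles yield feature records, and per-record provenance
(seen/complete/accepted) is preserved through gating.

The prominence gate is calibrated to the pipeline's noise floor (noise at a
few percent of a beat-bearing record's peak). It cannot reject *arbitrary*
beat-free noise normalized to its own maximum — 30 s of band-limited
Gaussian noise at unit peak always contains a few prominence-0.1 peaks.
That is a real limitation for records containing no heartbeats at all.

## Features, gates, medians

Interval A–B is `(t_B − t_A) × 1000` ms, oriented earlier→later (S1-J,
J-S2, S1-I, I-S2, S1-K, K-S2, I-J, J-K); slopes are rise-over-run of the
filtered BCG between wave extrema, in normalized units/s. Two identities
hold exactly by construction — `s1k = s1j + jk` and `s1j = s1i + ij` — and
serve as internal consistency checks.

The two-SD gates compute the pooled mean and *sample* standard deviation
(ddof = 1) over the whole raw dataset (pooled rather than per-subject; the
source is silent, and pooled statistics match the single global record
counts it reports). D1 bounds S1-J; D2 additionally bounds S1-K and I-J.
A zero-spread feature keeps all records. Because the rule is scale-free,
acceptance is invariant to affine rescaling of the dataset.

The robust "global estimate" of each feature for one session is the median
over its cycles (midpoint convention for even counts).

## Statistical characterization

Per feature and protocol state: sample mean/SD, a Gaussian-kernel density
estimate (Scott's-rule bandwidth), and the Shapiro–Wilk normality test
(skipped and flagged for n < 3 or zero spread). Feature-vs-SBP association
uses Pearson and Spearman correlations with two-sided p-values and a
straight-line fit under Huber loss — "Huber-regularized least squares" is
read as Huber-loss robust regression, tuning constant 1.345 (95% Gaussian
efficiency), fitted by IRLS (statsmodels RLM). Associations default to
per-session medians (the global estimates); per-cycle analysis is available
behind a flag.

## Regression

Splits are by subject (default 17 train / 4 test from a seeded random
permutation): no subject's beats may straddle the split, since
subject-specific timing baselines would otherwise leak. Model families and
published working points:

| family | hyperparameters (D1 / D2) |
|---|---|
| LR | — |
| SVR, RBF kernel | c=45, γ=1e-4, ε=0.01 / c=55, γ=1e-4, ε=0.01 |
| Kernel ridge, Laplacian | α=0.005, γ=0.05 (both) |
| Random Forest | 139 trees / 210 trees |

Kernel models see standardized features (train-set mean/SD — the source's
γ magnitudes suggest raw-scale input, but standardized training is the
safer default and a `scale_features=False` switch mimics raw-scale).
Trees and LR run on raw milliseconds. Grid search uses exhaustive 5-fold
CV on the training set only, scored by mean MAE (no criterion is named in
the source), ties keeping the earliest grid point.

Metrics: `EVS = 1 − Var(y−ŷ)/Var(y)` and `R² = 1 − SS_res/SS_tot`. The
source prints the coefficient of determination as the bare ratio
`SS_res/SS_tot` (without the "1 −"); we treat that as a typographical slip
— the ratio is the *unexplained* variance fraction and would invert the
reported model ranking — but emit both (`r2` and `unexplained_ratio`) for
transparency. The report also carries the signed mean error and its SD,
since clinical "mean error" usually means the signed mean difference rather
than the MAE. MDI importances are normalized to sum to one. Note that
scikit-learn forests are only *approximately* equivariant under feature
permutation (internal feature-order tie-breaking), so importance vectors
agree to ~1e-2, not bitwise.

## Synthetic cohort generator

The generator emulates a squat-exercise protocol: per-subject baseline SBP
~ N(112, 8²) mmHg drawn once; per-session state shifts N(+18, 5²)
(activity) and N(+2, 4²) (post-activity); heart rate per session from
N(70, 8²) / N(95, 10²) / N(78, 8²) bpm for rest/activity/post-activity;
30 s records at 1 kHz.

Per beat, the PCG is two Gaussian-windowed 40 Hz cosine bursts (σ = 15 ms;
amplitudes 1.0 and 0.7 for S1/S2) and the BCG is a Gaussian triplet
(negative I, positive J, negative K). The timing couplings are explicit
and linear:

* `t_J − t_S1 = 180 ms − 1.2 ms/mmHg × (SBP − 112) + N(0, 4 ms)`,
* `t_I = t_J − 45 ms`, `t_K = t_J + 55 ms` (I and K ride rigidly with J),
* `t_S2 − t_S1 = systole − 1.8 ms/mmHg × (SBP − 112) + N(0, 2 ms)`, with
  subject-level systole ~ N(320, 15²) ms.

The negative S2 coupling reflects the physiology that systolic ejection
time shortens under the sympathetic activation that raises pressure; its
net effect is a J-S2 slope of −0.6 ms/mmHg, matching the direction of the
J-S2/I-S2 associations the method is meant to recover, and it keeps the
S2-to-K gap inside the S2 search window across the SBP range. Setting
`s2_slope_ms_per_mmhg = 0` decouples S2 entirely. All magnitudes are
plausibility choices living in `SynthConfig`, never hard-coded; only the
*sign* of the S1-J coupling is treated as a modeling commitment.

Nuisance structure: beat-to-beat RR jitter (sd 20 ms), per-beat common BCG
amplitude scale (sd 0.10) plus small per-wave factors (sd 0.05), PCG burst
amplitude jitter (sd 0.10), additive white noise (sd 0.05 n.u.), and
0.3 Hz baseline wander (amplitude 0.1 n.u.). `SynthConfig.noiseless()`
zeroes every per-beat stochastic source while keeping subject-level
physiology, so each beat is an exact template copy (sessions are then
exact template sums to < 1e-12).

**Band-limited template calibration.** Wave *locations* are defined on the
band-limited signal — the hardware this emulates band-limits the BCG before
sampling. Raw Gaussian bumps placed naively at the nominal offsets would
have their filtered extrema dragged several ms by the 1–10 Hz band. The
generator therefore calibrates the raw triplet (centers, amplitudes,
widths) once per configuration by bounded least squares so that the
*filtered* template has its I/J/K extrema exactly at (−45, 0, +55) ms with
canonical amplitudes (−0.35, 0.70, −0.38); sub-sample extremum positions
use parabolic interpolation. The solve is deterministic, takes well under
two seconds, and is cached per configuration. Residuals are checked and
logged if they exceed 1 ms.

**Noise-equivalent SBP error.** With per-beat S1-J jitter sd σ and coupling
slope m, an ideal estimator reading a single cycle's S1-J makes mean
absolute error `σ·√(2/π)/|m|` (defaults: 4 ms, −1.2 ms/mmHg → 2.66 mmHg).
This is the yardstick for regression performance on default cohorts; models
at ~1× this floor have extracted essentially all per-beat information.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: no hemodynamic model (the SBP→interval coupling
is imposed, not emergent), no respiration or motion artifacts beyond
sinusoidal wander, no murmurs/ectopy/sensor dropouts, no inter-subject
variation in the coupling slope itself, and morphology far cleaner than
scale-measured BCG. Detection accuracy and regression errors here are
best-case; the value of the synthetic cohort is exercising the *machinery*
(ordering logic, windows, gates, splits, metrics) under known ground truth.

## Problem sizes and determinism

Default test problem sizes: full cohorts of 126 records × 30 s at 1 kHz for
detection/correlation checks; 10 independent cohorts for regression
stability; 100 seeded runs of a 400-record feature-level dataset for the
planted-importance check (waveform synthesis is bypassed there by
construction — only the S1-J column carries signal). Every stochastic step
(cohort draws, splits, forests) is seeded; identical seeds give
bit-identical cohorts and identical reports.

## Known limitations

* The S1 search window (0.3 s before J) assumes S1-J delays well under
  300 ms; pathologically long delays would push S1 out of the window.
* Very high heart rates (> 150 bpm) violate the default J refractory
  spacing and require retuning `min_jj_s`.
* The two-SD gates are pooled; with strongly subject-clustered intervals a
  per-subject gate would behave differently (not implemented).
* Beat-free records are not rejected wholesale (see the detection note);
  upstream quality control is assumed.
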