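# Methods

`neuroload` implements a four-level mental-workload detection pipeline for
hybrid EEG–fNIRS recordings of MATB-style multitask sessions, together with
a synthetic-session generator that reproduces the statistical structure the
analysis assumes. This note documents the models, the parameters that
matter, the numerical choices, and what the synthetic validation does and
does not establish about real recordings.

## The analysis protocol

A session consists of 4 task blocks of 3 minutes, one per difficulty level
(1, 3, 5, 7). EEG is recorded from 62 scalp electrodes plus two mastoids
(M1/M2) at 500 Hz with an ocular channel; fNIRS records O₂Hb and HHb
concentration changes at two prefrontal sites at 50 Hz.

Preprocessing is fixed-order. EEG: mastoid-average re-reference; 0.5–45 Hz
band-pass (Butterworth order 4, applied forward–backward for zero phase)
plus a 50 Hz notch (second-order IIR, Q = 30); resampling to 200 Hz with
FIR anti-aliasing (`scipy.signal.resample_poly`); ocular-artifact removal;
segmentation into 3-s windows on a stride grid anchored at each block
onset. fNIRS: moving-SD spike detection on the first difference (2-s flag
dilation, 3 SD threshold) with interpolation over flagged spans; 0.5 Hz
zero-phase low-pass; the same 3-s epoch grid, so EEG epoch *k* and fNIRS
epoch *k* cover identical wall-clock windows.

Ocular artifact removal defaults to regressing each scalp channel on the
ocular reference channel and subtracting the fitted contribution. This is
deterministic and directly testable against the generator's retained
artifact-free ground truth. A FastICA mode (components zeroed when their
correlation with the ocular channel exceeds 0.7) is available for users who
prefer a decomposition-based cleanup; it is not the default because
component selection criteria are inherently heuristic.

Features per epoch:

* **EEG band powers** — Welch PSD (1-s Hann segments, 50% overlap)
  integrated over θ (3–8 Hz), α (8–13 Hz), β₁ (13–20 Hz), β₂ (20–30 Hz)
  per channel; 62 × 4 = 248 columns on the full montage.
* **Pair differences** — power(a) − power(b) for seven fixed pairs
  (P8–P7, O2–O1, C2–C1, P4–P3, Pz–O1, Pz–O2, O1–AF3) per band; 28 columns.
* **fNIRS statistics** — 11 descriptors per (site, chromophore) trace:
  mean, SD, mean squared deviation, skewness, RMS, peak (max |x|), crest
  factor (peak/RMS), kurtosis, waveform factor (RMS/mean|x|), pulse factor
  (peak/mean|x|), margin factor (peak/(mean √|x|)²); 44 columns. "Mean
  squared error" is implemented as the biased variance (mean squared
  deviation from the trace mean) — the descriptor list names it without
  defining it, and this is the standard signal-descriptor reading. The
  factor definitions are the standard vibration-analysis forms.
* **Neurovascular coupling (NVC)** — zero-lag Pearson correlation between
  each chromophore's amplitude time-course and the frontal EEG band-power
  time-course within the epoch; 4 columns. The band-power course is
  computed at AF3 (mean over the four bands) in 0.5-s sliding windows with
  0.25-s hop, and the chromophore trace is sampled at the same window
  centers. Channel, window, hop, and band pooling are configurable; AF3 is
  the default because the frontal site lies nearest the fNIRS optodes.

Feature sets: only-EEG = per-channel powers + pair differences (276 columns
full montage, 132 on the 26-channel optimized montage); only-fNIRS = the 44
statistical descriptors; fused = optimized EEG + fNIRS statistics + NVC =
180 columns. The NVC features require EEG, so they belong to the fused set
only — the only assignment consistent with the printed widths (44 vs 48 and
132 + 48 = 180).

Outlier removal drops, per subject, every epoch containing any feature with
|z| > 3 (z-scores per subject and column). With hundreds of columns this
removes a substantial fraction of rows (roughly half at 300+ columns for
Gaussian-like features); the rule is row-wise because downstream sample
counts are reported per dataset. Row-drop severity scales with column
count — a caveat to remember when adding features.

**Channel screening.** Per subject, the 248 band-power features are ranked
by recursive feature elimination around a linear-kernel SVM (C = 1,
eliminating 10% of remaining features per iteration; features standardized
first) and the top 100 kept. A feature's importance weight is the number of
subjects whose top-100 set contains it; a channel's weight sums its four
band features' weights. Channels are ranked by weight (ties broken by
montage order). The linear kernel is used because elimination requires
feature weights, which the RBF classifier of the final model does not
provide. An accuracy-vs-channel-count curve (RBF SVM per subject on the
top-n channels' band powers, stratified 80/20 split) determines the
optimized montage: the smallest n at which the 3-point moving average of
per-channel accuracy gain falls below 0.5 points. The 26-channel montage
published for this protocol ships as a packaged constant
(`OPTIMIZED_MONTAGE_26`) for reproduction mode.

**Classification.** One model per subject (summaries across subjects),
stratified 80/20 split, grid search with fivefold CV on the 80%, winner
refit on the full 80%. Grids: SVM (RBF) C ∈ {0.0001, 0.001, 0.01, 0.1, 1,
10, 20, 30} × γ ∈ {0.1, 0.2, 0.25, 0.4, 0.8, 1.6, 3.2, 6.4}; decision tree
criterion {entropy, gini} × max depth {10, 30, 60, 100} × min split
{2, 5, 10, 15}; random forest trees {100, 200, 500}; remaining
hyper-parameters at scikit-learn defaults, recorded in the run manifest.
Standardization lives inside the estimator pipeline, so its statistics are
fit on training folds only; a test asserts this directly. A two-way ANOVA
(feature set × classifier, per-subject accuracies as replicates) tests the
main effects and interaction.

**Statistical report.** Behavioral composites min–max normalize each
NASA-TLX dimension (and each performance indicator, negating response time
and deviations first so larger = better) across the input and average the
six components. Level effects are one-way ANOVAs with Benjamini–Hochberg
FDR on the post hoc pairwise comparisons (a Bonferroni switch is provided;
the protocol literature mixes the two labels and BH is the less
conservative, better-calibrated default for the hundreds of scalp tests).
The scalp map runs the ANOVA per (channel, band) with one FDR family over
all 248 tests; post hoc pairs form their own family. The contrast map is
the level-7 minus level-1 mean band power per cell, averaged across
subjects.

## The synthetic generator

The generator is the study-conditions oracle: every downstream property is
validated against what it injected.

* **EEG** — per channel, a sum of four band-centred sinusoids (5.5, 10.5,
  16.5, 25 Hz) with random phase per 3-s segment, baseline amplitudes
  (4, 5, 2.5, 1.8 μV), plus 1/f pink noise (SD 2 μV × `noise_sd`).
  Difficulty modulates amplitudes through the transformed level scale
  s^κ, with s = (level−1)/6 and κ = `eeg_modulation_exponent` = 2 by
  default (scalp power responds weakly at low loads, strongly at high
  loads): θ rises frontally (slope +0.8 × `effect_size`), α falls (−0.5)
  and β₁/β₂ rise (+0.8) occipitally. A
  `modulation_overrides` map can redirect the modulation to arbitrary
  channels (used by the channel-recovery checks), and
  `band_amplitude_overrides` can silence bands (used by the
  spectral-placement check). Ocular transients are exponential-decay
  kernels (τ = 0.15 s, ~120 μV) at Poisson onsets (0.25 Hz) on the EOG
  channel, mixed into frontal channels with fixed prefix-based weights
  (Fp 0.5, AF 0.35, F 0.18); the artifact-free frontal channels are
  retained as ground truth.
* **fNIRS** — per block, a gamma-CDF rise (shape 3, scale 4 s; a smooth
  double-gamma-like saturation over ~20 s) to a difficulty-dependent
  plateau: O₂Hb 0.4 + 1.6·`effect_size`·s^σ μmol/L, HHb −0.1 −
  0.6·`effect_size`·s^σ (right site at 0.9 gain), with σ =
  `fnirs_saturation` = 0.5 by default. The exponent compresses the
  vascular response at high load, so the chromophores separate the low
  levels better than the high ones, while the supralinear EEG modulation
  (κ = 2 above) resolves the top levels: the two modalities carry
  complementary information, which is the premise behind fusing them (and
  the reason a fused model can beat the better single modality rather
  than merely tie it). Physiological noise is a 0.1 Hz Mayer-wave and a 0.25 Hz
  respiratory sinusoid plus white noise, all scaled by 0.08 μmol/L ×
  `noise_sd`.
* **Behavior** — TLX dimension means 25 + 50·`effect_size`·s (0–100 scale,
  small fixed per-dimension offsets), performance indicators with
  level-linear degradation (e.g. monitoring response time
  0.6 + 0.9·`effect_size`·s seconds, accuracy 0.97 − 0.35·`effect_size`·s),
  Gaussian jitter scaled by `noise_sd`.

`noise_sd` is a dimensionless multiplier on the per-modality base noise
scales rather than a single physical unit, since EEG (μV) and fNIRS
(μmol/L) units differ. `effect_size` = 0 produces exchangeable null data.
Everything is deterministic given `(seed, subject_id)` (per-subject streams
derived via CRC32 of the subject label).

No published effect magnitudes exist for this protocol, so the defaults
(`effect_size` = 1, `noise_sd` = 1) were calibrated once to make the
monotone trends detectable in cohorts of a few subjects; they produce
cleaner class separation than real scalp recordings. The validation
cohorts therefore use two regimes: the default regime for trend/recovery
checks, and a high-noise regime (`noise_sd` = 6) for the fused-vs-unimodal
ordering comparison, chosen so that neither modality classifies at ceiling
— an ordering cannot be exhibited by saturated accuracies. In that regime
the complementary sensitivity ranges make the fused advantage structural
(each unimodal model confuses the level pair its modality is least
sensitive to; the fused model resolves both), rather than an artifact of
one lucky cohort.

### What the generator does not emulate

No volume conduction or leadfield mixing (channels are independent up to
shared modulation), no real EEG microstructure (bursts, spindles,
non-stationarity), no optical-density/Beer–Lambert stage (fNIRS is
generated directly in concentration units), no task software, and no
subject-level heterogeneity in effect direction. Passing the recovery
checks therefore demonstrates that the pipeline's stages measure what they
claim under known ground truth — not that the published accuracy figures
transfer to new human data, which would require the original (undeposited)
recordings.

## Numerical choices and degenerate inputs

* Welch band power integrates PSD bins over [lo, hi) with a 1 Hz bin width
  (1-s segments at 200 Hz); it matches a single-taper periodogram integral
  within 5% on noiseless sinusoids (tested).
* Zero-variance traces: skewness/kurtosis defined as 0; ratio descriptors
  with zero denominators return 0; constant series in the NVC correlation
  return 0. All are logged.
* Epoch grids: floor((block − length)/stride) + 1 windows per block;
  windows crossing a block end are skipped with a warning.
* Resampling 500→200 Hz uses a rational 2/5 polyphase FIR; passband ripple
  is ~10⁻⁴ relative.
* Ties in the channel ranking break by montage order; RFE uses a fixed
  elimination fraction, so results are deterministic.
* All RNG-dependent stages (splits, CV folds, forests, permutations) take
  explicit seeds recorded in the run manifest.

## Problem sizes

The packaged validation runs use scaled cohorts chosen to exercise every
stage while keeping a full run in minutes on one CPU: 30–60 s blocks for
unit-level checks, full 180-s blocks with 5 subjects for the
fused-ordering cohort, 4 subjects for null calibration (5 label
permutations per subject), and 2 subjects for the trend-recovery pooled
maps. Stage timings scale linearly in subjects and block duration; a
20-subject, 180-s-block cohort is practical but takes tens of minutes.

## Known limitations

* The row-wise |z| > 3 outlier rule is aggressive at high column counts.
* The regression-based ocular cleanup removes only activity correlated
  with the ocular channel; ICA mode exists but its component threshold is
  heuristic.
* The accuracy-vs-channel-count curve uses a fixed-hyper-parameter RBF SVM
  (not the full grid) for tractability; the plateau location is therefore
  approximate.
* Synthetic fNIRS noise is stationary; real recordings show slow drifts
  and motion spikes beyond the modeled spike type.
* With one block per level, slow physiological noise is partially
  confounded with level; label permutation is used for null calibration
  for exactly this reason.
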