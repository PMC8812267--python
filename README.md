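# neuroload

A tested, reusable pipeline for **four-level mental-workload detection from
hybrid EEG–fNIRS recordings** of MATB-style multitask sessions, aimed at
neuroergonomics researchers who want to analyze (or prototype against)
combined scalp-EEG + prefrontal-fNIRS workload protocols without access to
proprietary recordings.

The pipeline covers, end to end:

* **Synthetic session generation** — MATB-like sessions (4 blocks × 3 min,
  difficulty levels 1/3/5/7) with difficulty-monotone θ/α/β band-power
  modulation, hemodynamic O₂Hb/HHb level effects, ocular artifacts, 1/f
  noise, and NASA-TLX / performance tables, all with retained ground truth
  for recovery testing.
* **Preprocessing** — mastoid re-reference, 0.5–45 Hz zero-phase Butterworth
  band-pass + 50 Hz notch, resampling to 200 Hz, ocular-artifact removal,
  and aligned 3-s epoching of both modalities; fNIRS motion correction and
  0.5 Hz low-pass.
* **Feature battery** — Welch band powers in θ (3–8), α (8–13), β₁ (13–20),
  β₂ (20–30 Hz) per channel; seven channel-pair power differences; 11
  statistical descriptors per chromophore trace; neurovascular-coupling
  correlations between frontal band power and chromophore amplitude.
* **Channel screening** — per-subject SVM recursive feature elimination on
  the 248 band-power features, cross-subject importance aggregation
  (feature weight = subjects retaining it; channel weight = sum over its
  four bands), accuracy-vs-channel-count curve, and plateau-based montage
  selection. The published 26-channel optimized montage ships as
  `OPTIMIZED_MONTAGE_26`.
* **Classification** — only-EEG / only-fNIRS / fused feature sets evaluated
  per subject with SVM (RBF), decision tree, and random forest under a
  stratified 80/20 split + fivefold-CV grid search, plus a two-way
  feature-set × classifier ANOVA.
* **Statistical report** — behavioral composite scores, per-channel
  difficulty ANOVAs with Benjamini–Hochberg FDR over the 62 × 4 scalp
  family, high-minus-low band-power contrast maps, and chromophore level
  effects.

The core quantity is the per-channel band power
P(ch, b) = ∫_b S_ch(f) df, the Welch PSD integrated over each band; the
fused feature vector per 3-s epoch stacks the optimized-montage band
powers (26 × 4), the pair differences (7 × 4), the fNIRS descriptors
(2 × 2 × 11), and the NVC correlations r(P_AF3(t), [chromo](t)) at lag 0
(4), giving the 132 + 44 + 4 = 180-dimensional fused set.

## Worked example

```bash
python examples/02_features.py
```

prints (on this machine):

```
80 EEG epochs of 600 samples (62 scalp channels at 200 Hz)
     full montage: {'only_eeg': 276, 'only_fnirs': 44, 'fused': 324}
optimized montage: {'only_eeg': 132, 'only_fnirs': 44, 'fused': 180}
outlier removal (|z| > 3 per subject): 80 -> 54 epochs
```

The 276 columns are the full-montage EEG battery (62 channels × 4 bands +
7 pairs × 4 bands); restricting to the 26-channel optimized montage gives
132; the fNIRS statistical battery is 44 wide; and the fused set is
180 = 132 + 44 + 4 NVC correlations. The outlier stage drops whole epochs
containing any per-subject feature |z| > 3.

Other examples (each prints what it computes and what it means):
`01_generate_session.py` (signal model and ground truth),
`03_channel_ranking.py` (RFE importance recovers injected channels),
`04_classification.py` (fused vs unimodal accuracy), `05_statistics.py`
(scalp FDR maps, contrasts, chromophore level effects).

A thin CLI wraps the same pipeline:

```bash
neuroload run --out results/run1 --seed 7 --subjects 5 --reference-montage
neuroload simulate --out data/ --seed 1 --subjects 2
```

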