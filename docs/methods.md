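# Methods

This note documents the models, numerical choices and known limits of
`fnirsdecode`. It is the package's own account of its science; every number
quoted here is computed by the test suite or the examples, not asserted from
elsewhere.

## Signal model and optics

A channel is one source–detector pair at 30 mm separation, measured at 760
and 850 nm. The modified Beer–Lambert law relates optical-density change to
chromophore concentration change,

    ΔOD(λ, t) = [ε_HbO(λ) ΔHbO(t) + ε_HbR(λ) ΔHbR(t)] · d · DPF(λ),

with base-10 molar extinction coefficients from the standard compiled
hemoglobin tables (Prahl/Gratzer; 760 nm: ε_HbO = 586.0, ε_HbR = 1548.52;
850 nm: ε_HbO = 1058.0, ε_HbR = 691.32, all in M⁻¹cm⁻¹), d = 3 cm, and
differential pathlength factors 7.25 (760 nm) and 6.38 (850 nm). The
"respectively" that pairs the two DPF values with the two wavelengths is read
in wavelength order; the chromophore-order alternative can be passed through
the `dpf` argument. Forward (simulation) and inverse (preprocessing)
directions share one constants table, so their composition is an exact
algebraic identity (round-trip error below 1e−9 µM, verified to 1000 random
samples).

## Preprocessing

Stage order is fixed: band-pass filter each wavelength's intensity record,
whole-record linear detrend, optical density, Beer–Lambert inversion,
segmentation.

* **Filter.** Windowed-sinc (Hamming) linear-phase FIR, pass band
  0.01–0.1 Hz, transition width 0.02 Hz → 861 taps at 5.2083 Hz. The
  symmetric kernel is applied with centred convolution and reflection
  padding, so the group delay is fully compensated (zero net phase). The
  taps are re-centred to sum exactly to zero, turning the −46 dB DC leak of
  the raw design into an exact null. Realised response: ≥ 20 dB attenuation
  at DC and 0.3 Hz (cardiac/respiratory bands are far below −20 dB), ripple
  within ±1 dB across 0.02–0.08 Hz.
* **DC handling.** A band-pass removes the mean intensity, which would break
  the subsequent logarithm. The filter and detrend therefore act on the
  fluctuation around the per-channel whole-record mean I₀, and optical
  density is computed from I₀ + fluctuation. For fNIRS-sized fluctuations
  (|ΔOD| ≪ 1) this is the linear-regime reading of "filter the raw data";
  the quadratic term it neglects is of order ΔOD²·ln10/2.
* **Segmentation.** Half-open windows [onset, onset + 30 s), length
  floor(30 × fs) = 156 samples, 0-based indices. Out-of-bounds trials raise
  an error naming the trial.

## Features

Each trial segment and channel/chromophore is reduced to the average of
moving 2-s window means at 50 % overlap. The non-integer window length
(2 s × 5.2083 Hz = 10.42 samples) is rounded to 10 samples with hop 5;
only full windows count, so a 156-sample segment averages
floor((156 − 10)/5) + 1 = 30 window means. Trailing samples outside a full
window are ignored — the conservative reading of an unstated rounding rule.
Columns are ordered HbO block then HbR block, montage channel order inside
each block, so model weights map deterministically onto channel maps.

## Classifier

Two-class Fisher LDA with equal priors: pooled (unbiased) within-class
scatter S_w, discriminant w = S_w⁻¹(μ₁ − μ₂), bias at the midpoint of the
projected class means. Ties (score exactly 0) go to the first class label.
If cond(S_w) > 1e10 the fit shrinks S_w ← (1−γ)S_w + γ·tr(S_w)/p·I with
γ = 0.1; the `shrinkage` field records what was used, and the scale-
invariance and closed-form tests pin the γ = 0 path. Predictions agree with
an independent reference implementation on ≥ 99 % of labels across 100
random well-conditioned problems.

## Feature selection

The selection step ranks "eigenvalues of the within-class covariance" —
a phrase that does not pin down a per-feature score, so the package fixes
one and documents the choice. The default scorer (`scatter-eig`) is the
per-feature loading of the whitened class-mean difference computed from the
eigen-decomposition of S_w:

    score = | V Λ^(−1/2) Vᵀ (μ₁ − μ₂) |   (elementwise),

i.e. the discriminative direction after whitening by S_w^(1/2) rather than
the full S_w⁻¹. The absolute discriminant loading |w_i| is available as
`abs-weight`. The whitened scorer is the default because the full-inverse
weights are unstable at this problem's trials-to-features ratio
(~180 trials for 64 features): features with small variance receive inflated
S_w⁻¹ weights, and in planted-effect simulations |w_i| ranking recovered the
three planted channels in at most a quarter of runs, while the whitened
scorer recovers them in ~86 % of 50 runs at the default generator settings
(and yields higher downstream accuracy). Ranking is descending with ties
broken by lower feature index (stable). Subset sizes are
max(1, floor(fraction × 64)): 3, 12 and 19 features at 5 %, 20 % and 30 %.

## Evaluation

Cross-cohort: rank on the pooled training cohort, fit on the selected
columns of all pooled training trials, then score each test subject's trials
independently with balanced accuracy (mean of the two per-class recalls,
in percent) — insensitive to the 5-vs-10 class imbalance; any constant
predictor scores 50 %. A leave-one-subject-out variant re-ranks and refits
per fold with the held-out subject fully excluded. No per-subject
normalisation is applied by default.

## Statistics

Two-sided tests throughout. One-sample t against 50 % per
(task, comparison, fraction), Bonferroni m = 120 (20 fractions × 3
comparisons × 2 tasks). Two-sample Student t (equal variances; Welch
selectable) on per-subject mean valence/arousal ratings, m = 12. Spearman
rank correlations (midrank ties) between best accuracies and the 16 pre-mood
items and 16 post-minus-pre deltas, m = 64; constant inputs yield a flagged
result with p = 1. Degenerate zero-variance t-tests return t = 0, p = 1
when the mean equals the null value. The mood scale reserves 16 item slots
although the instrument lists 15 adjectives; the 16-measure correction
family is kept and the discrepancy is surfaced here rather than resolved.

## Synthetic cohorts

The generator emulates the study design: two independent cohorts (nominal
49 and 20 subjects, scalable), 20 trials per task (5/10/5), 30-s blocks,
2-s baselines, uniform 2–4-s gaps, ratings drawn per (task, condition) from
the pooled means/sds of the study's rating table (clipped to [1, 9]), and a
16-item eleven-point mood scale pre/post with no true accuracy correlation.

* **Response kernel.** Canonical double-gamma HRF (peak 6 s, undershoot
  16 s, ratio 1/6), sampled with the dt factor so a unit 30-s boxcar peaks
  near 1; "amplitude" is therefore the peak micromolar block response.
* **Planted effects.** ΔHbR only, mirroring the reported channel effects:
  positive → +0.08 µM on 6-7; neutral → +0.08 µM on 5-4 and 4-4. ΔHbO
  effects are configurable but off by default.
* **Noise.** Per channel and chromophore: Mayer-wave sinusoid (0.1 Hz,
  0.2 µM), respiration (0.3 Hz, 0.15 µM), subject-specific cardiac
  (uniform 0.8–1.2 Hz, 0.25 µM), white noise (0.25 µM sd), linear drift
  (slope sd 0.002 µM/s), all with per-subject random phases; HbO noise is
  doubled (physiological noise dominates HbO in practice). Two variability
  terms are also classed as noise amplitudes: a per-subject responder
  multiplier (Gaussian, sd 0.5, truncated at 0 — a disengaged subject shows
  no response rather than an inverted one) and per-trial amplitude jitter
  (Gaussian, sd 0.45). Setting every amplitude to zero recovers the exact
  convolution oracle.
* **Calibration.** The study reports no effect sizes in µM, so the planted
  amplitude and noise defaults were fixed once so that scaled-down cohorts
  (12 train / 6 test) land in the study's accuracy regime rather than at
  ceiling: positive-vs-neutral active decoding averages ≈ 80 ± 13 % with
  ~86 % top-3 recovery of the planted channels over 50 runs. Accuracy and
  recovery trade off through the subject-level variability (it damps
  transfer to unseen subjects but corrupts pooled ranking), and these
  defaults sit deliberately on the recovery side of that trade-off.
* **Determinism.** All randomness flows from one master seed through named
  spawned streams (PCG64); identical seeds give byte-identical on-disk
  cohorts, recorded as per-file sha256 in the manifest. Baseline intensities
  are drawn log-uniformly in [0.1, 1] arbitrary units — only ratios enter
  the analysis.

**What the generator does not model:** motion artifacts, short-separation
channels or other systemic-physiology regressors, spatial noise correlations
between neighbouring channels, within-subject rating correlations, realistic
quasi-periodic (drifting-phase) Mayer waves, or task-evoked systemic
responses. Passing tests therefore demonstrate the correctness and the
statistical behaviour of the analysis chain under its own assumptions, not
decoding performance on real recordings.

## Problem sizes

Simulation-heavy checks use deliberately scaled cohorts: 12 train / 6 test
subjects for planted-effect recovery and permutation chance level (50 seeds
and 100 permutations respectively), 6 train / 4 test for the 200-pipeline
null calibration of the corrected accuracy tests. The defaults
(49/20 subjects, both tasks) remain available through `SimParams`.

## Known limitations

* The TSV recording dialect is the only on-disk format; vendor formats and
  HDF5 containers are out of scope.
* The eigenvalue-to-feature mapping of the original selection step is not
  recoverable from its description; both implemented scorers are principled
  readings, and results at small subset fractions depend on which is used.
* Cross-trial leakage through the 0.01 Hz high-pass (a trial's response
  bleeds, sign-flipped, into neighbouring trials' windows) is a property of
  the prescribed filter, not removed by the package; it bounds achievable
  feature contrast at ~20 % of the planted peak amplitude.
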