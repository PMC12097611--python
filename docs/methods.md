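# Methods

## Scope and model

The package implements a binary-decoding stack for paired EEG and
functional transcranial Doppler (fTCD) trials: filter-bank common spatial
patterns (FBCSP) for EEG, maximal-velocity envelope features for fTCD,
linear-SVM evidence projection per modality, and a weighted Bayesian
fusion of the two evidence streams with Gaussian-KDE class-conditional
densities. It covers offline, subject-specific analysis of two visual
paradigms — motor imagery (left / right / baseline) and flickering mental
rotation / word generation with 7 Hz and 17 Hz steady-state responses —
and deliberately excludes acquisition control, online decoding, artifact
handling and cross-subject transfer.

## EEG stage

* **Filter bank.** Nine non-overlapping 4th-order Butterworth band-pass
  filters of 6.5 Hz bandwidth spanning 2–60 Hz, applied forward–backward
  (zero phase) so trials stay time-aligned. 2 + 9 × 6.5 = 60.5 Hz
  overshoots the stated 60 Hz ceiling, so the last band is clipped to
  [54, 60] — this respects the band count and the frequency range
  simultaneously.
* **CSP.** Per band, trial covariances are trace-normalized and averaged
  per class; the filters solve the symmetric-definite generalized
  eigenproblem `Σ⁺w = λ(Σ⁺+Σ⁻)w`. When the composite matrix `Σ⁺+Σ⁻` is
  well conditioned (condition number < 1e10) the problem is solved
  exactly, so the whitening identity `Wᵀ(Σ⁺+Σ⁻)W = I` and the eigenvalue
  complementarity `λ⁺+λ⁻ = 1` hold to machine precision; only
  rank-deficient or near-singular composites receive a relative ridge
  `(1−γ)Σ + γ(tr Σ/n)I` with γ = 1e-6. A fixed always-on ridge would bias
  the eigenvalues by ~1e-6, which is visible at the 1e-8 tolerance the
  identities are tested at.
* **Determinism.** Eigenvector signs are fixed (largest-magnitude entry
  positive) and equal eigenvalues keep solver order via a stable sort, so
  fitted filters are reproducible across linear-algebra backends.
* **Features.** Log variance of the projections on the `Nf` top and `Nf`
  bottom filters, band-major concatenation, `9 × 2Nf` per trial,
  unnormalized (no division by the summed variance), with `Nf` swept over
  1–8.

## fTCD stage

* **Envelope.** One-sided, energy-preserving STFT power spectrogram
  (Hann window, 75% overlap); per frame, the highest bin with power at
  least 10% of the frame peak; conversion through the Doppler relation
  `v = f_d c / (2 f_t cosθ)`; 5-frame median smoothing. The default
  speed of sound is c = 1540 m/s and θ = 0 (standard fTCD convention when
  the insonation angle is unknown); c only rescales velocities linearly
  and cannot affect classification after standardization.
* **Window length 32 ms.** The spectral edge chirps rapidly during the
  systolic upstroke (hundreds of Hz within ~0.1 s). With long windows
  (≥100 ms) that chirp smears across tens of bins and biases the traced
  edge by several bins; 32 ms windows (≈31 Hz ≈ 1.2 cm/s resolution,
  125 Hz frame rate) keep the mean tracing error within one bin of the
  true velocity while frame-rate remains far above cardiac dynamics.
* **Noise floor.** The floor is estimated as the median frame power of
  the lowest-energy decile; a frame is flagged as noise-only (velocity 0)
  when it both fails to clear the floor by 3 dB and sits below a quarter
  of the trial's median frame power. The second condition prevents
  homogeneous all-signal trials — whose lower decile is close to the
  bulk — from flagging anything.
* **Feature catalogue (version `v1`, 47 per side, left/right
  concatenated).** Statistical: mean, variance, skewness, kurtosis,
  median absolute deviation, IQR, 10 relative histogram counts, ECDF
  percentiles 5/25/50/75/95. Temporal: autocorrelation lags 1–5,
  zero-crossing rate, peak count, mean peak-to-peak amplitude, mean
  slope, line length, sample entropy (m = 2, r = 0.2 σ). Spectral: total
  power, centroid, spread, 85% roll-off, cardiac-band (0.7–2 Hz) power,
  and per-level energies and spreads of a 4-level db4 wavelet
  decomposition. Constant envelopes yield defined zeros, never NaN.
* **Screening.** Two-sided Wilcoxon rank-sum per feature: exact null
  distribution for combined n ≤ 20 without ties, otherwise the normal
  approximation with midrank tie correction and *no* continuity
  correction — the continuity correction is measurably conservative at
  the trial counts screened here (achieved level ≈ 0.047 instead of
  0.050 at 25 + 25 trials). If no feature passes p < 0.05 the single
  best feature is kept (flagged), so the fTCD evidence stream never runs
  empty.

## Fusion stage

* **Evidence.** Linear-kernel SVM (cost C = 1 by default) on features
  standardized with training-fold statistics; the raw signed decision
  value is the evidence score.
* **Densities.** Gaussian KDE per class and modality with Scott's
  bandwidth `h = σ̂ n^(−1/5)`, evaluated in log space and floored at
  1e-300 so far-tail test scores never produce 0/0 ratios. If a class's
  training scores are exactly constant (possible when a single discrete
  feature survives screening) the bandwidth falls back to 1e-3 times the
  pooled score scale instead of failing.
* **Decision.** `argmax_X α·log p(e|X) + (1−α)·log p(f|X) + log p(X)`
  with uniform priors; exact ties go to the first class in the model's
  class order. α is searched over 0, 0.01, …, 1; ties toward the
  smallest α. Because the grid contains 0 and 1, the best fused
  validation accuracy can never fall below either single-modality
  accuracy, and α = 1 / α = 0 reproduce the single-modality rules
  exactly.
* **Identifiability of α.** When one stream's evidence densities are
  perfectly separated, its log-density ratios saturate and every α above
  a small threshold attains identical accuracy; the smallest-α tie-break
  then returns the left edge of that plateau. α is therefore only
  informative in the overlapping-evidence regime, and the recovery
  experiments are run there.
* **Cross-validation.** Stratified folds with seeded shuffling. In the
  default `nested` mode, screening, projectors, KDEs, `Nf` and α are all
  chosen inside the training folds (inner 75/25 validation split); the
  `paper` mode instead selects `Nf` and α post hoc by maximum mean
  test-fold accuracy, reproducing maximum-accuracy reporting styles —
  useful for comparison, optimistic by construction. Reported
  single-modality accuracies use the same KDE decision rule at α = 1
  (EEG) and α = 0 (fTCD); SVM sign-rule accuracies are reported alongside
  as diagnostics.
* **Reporting statistics.** Paired accuracy comparisons use the one-sided
  Wilcoxon signed-rank test (exact for ≤ 25 nonzero differences, zeros
  dropped). The per-subject optimal α values are tested against the
  equal-weight value 0.5 with a one-sample signed-rank test by default; a
  literal two-sample rank-sum backend against a constant 0.5 sample is
  provided because the one-sample design is sometimes described by that
  name.

## Synthetic data

The generator is the package's ground-truth surface, not a physiological
model.

* **EEG.** Four sources mixed into the channels by a full-column-rank
  random matrix: two class-informative sources (motor imagery: mu 8–13 Hz
  plus weaker beta 14–30 Hz band noise whose power is suppressed
  contralaterally by the imagined side; flickering paradigm: 7 Hz and
  17 Hz narrowband components present only for the class attending them)
  and two broadband 2–60 Hz background sources, plus white sensor noise
  at a configurable SNR. Class gains multiply source *power*. Defaults
  follow the acquisition regime: 16 channels, 256 Hz, 10 s trials.
* **fTCD.** Per side, a pulsatile velocity waveform
  `v(t) = v₀(1 + 0.4·cardiac(t)) + offset` with a raised-cosine systolic
  upstroke (15% of the cycle) and exponential diastolic decay (τ = 25%),
  v₀ = 60 cm/s, heart rate 1.2 Hz. The raw signal is a sum of 25
  randomly phased scatterer tones at stratified fractions of the
  instantaneous maximal Doppler shift — stratification keeps consecutive
  scatterers spectrally resolvable so no slow beat blanks the spectral
  edge — with the fastest scatterer pinned at the edge with unit
  amplitude (vessel-center blood moves fastest and reflects strongly).
  White noise enters at a configurable floor. Class structure is a
  lateralized velocity offset (default 8 cm/s on the task-relevant side);
  per-trial, per-side baseline jitter (σ = 3 cm/s) models the
  trial-to-trial variability of cerebral blood flow, without which the
  mean-velocity feature would be noise-free and any offset would saturate
  accuracy. Defaults: 8820 Hz (44.1 kHz decimated by 5), 10 s trials.
* **What it does not model.** Volume conduction of real scalp EEG,
  artifacts (blinks, probe motion), nonstationarity within a session
  (trials are i.i.d.), bidirectional flow, vessel anatomy. Passing tests
  therefore demonstrate correctness of the *pipeline*, not expected
  accuracy on human recordings.

## Validation studies and problem sizes

The studies in `neurofuse.validation` (shared by the test suite and
`scripts/acceptance.py`) run at desk scale as the package's own choice of
study size: 8-channel, 128 Hz, 3 s EEG trials with a 4-band 2–30 Hz bank;
2 s Doppler trials at 8820 Hz; 20–25 trials per class.

* **Envelope recovery** — 3 trials × 2 sides, noiseless and 20 dB SNR;
  mean absolute tracing error vs. the exact v(t), and their correlation.
* **Screen calibration** — 50 null replicates (zero offsets) × 94
  features at 25 trials/class. The catalogue's features are strongly
  correlated within a replicate (distribution summaries, ECDF
  percentiles and wavelet energies overlap heavily; measured design
  effect ≈ 9), so the selected fraction is compared to the nominal 5%
  with an interval based on the between-replicate variance, not on an
  independent-count binomial width.
* **α recovery** — 11 informativeness levels × 10 replicates sweeping
  the EEG class gain (1.0 → 0.65 power) against the Doppler offset
  (5 → 0 cm/s), both inside the overlapping-evidence regime; per
  replicate the α grid-search curve is averaged over 5 stratified
  train/validation splits before the argmax, which removes the heavy
  argmax noise of a single small validation set. Monotonicity of the
  per-level mean α is summarized by Spearman ρ.
* **Gaussian-limit fusion** — 2000 training and 2000 test points with
  unit-variance Gaussian class scores at ±1; agreement of the KDE fusion
  decision at α = 0.5 with the closed-form Bayes rule `e + f > 0`.

## Known limitations

* α is reported but weakly identified whenever either modality separates
  its classes perfectly (see above).
* The feature catalogue is a fixed, versioned stand-in for an external
  catalogue whose exact composition is not published; results depend on
  the version tag recorded in every feature vector.
* The rank-sum screen is mildly conservative for heavily tied discrete
  features (peak counts, histogram counts); the pooled null level is
  ≈ 0.048 rather than 0.050.
* `paper` mode is intentionally optimistic (selection on test folds) and
  should not be used to estimate generalization.
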