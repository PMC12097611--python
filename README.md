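# neurofuse

Analysis pipeline for **multimodal EEG–fTCD brain–computer interfaces**:
filter-bank common spatial patterns (FBCSP) for EEG, maximal-velocity
envelope features for functional transcranial Doppler ultrasound (fTCD),
per-modality linear evidence projection, and weighted Bayesian fusion with
kernel density estimates, evaluated under stratified cross-validation.

It is written for BCI researchers who want a tested, reproducible
implementation of this decoding stack — including a synthetic-data
generator with known ground truth, so every stage can be validated without
access to human recordings.

## The method

**EEG.** Each trial `E` (channels × samples) is band-pass filtered into
nine non-overlapping 6.5 Hz bands spanning 2–60 Hz. Per band, with
trace-normalized trial covariances `C = E Eᵀ / tr(E Eᵀ)` and class-mean
covariances `Σ⁺, Σ⁻`, CSP filters solve

    Σ⁺ w = λ (Σ⁺ + Σ⁻) w,      Wᵀ(Σ⁺ + Σ⁻)W = I,  λ⁺ + λ⁻ = 1,

and the trial feature is the log variance of the signal projected on the
`Nf` filters from each end of the eigenvalue spectrum — `9 × 2Nf` features
per trial.

**fTCD.** The raw Doppler audio is a sum of echoes from scatterers moving
at different speeds; a scatterer at velocity `v` shifts the carrier by
`f_d = 2 f_t v cosθ / c`. Per STFT frame, the highest frequency bin whose
power reaches 10% of the frame peak is converted through this relation to
the **maximal flow velocity envelope**; a fixed catalogue of statistical,
temporal and spectral descriptors of the left and right envelopes is
screened by a two-sided Wilcoxon rank-sum test at p < 0.05.

**Fusion.** A linear-kernel SVM per modality maps features to a scalar
evidence score; class-conditional score densities are estimated by
Gaussian KDE with Scott's bandwidth `h = σ̂ n^(−1/5)`, and a test trial
with evidences `(e, f)` is assigned

    argmax_X  p(e|X)^α · p(f|X)^(1−α) · p(X),

with uniform prior and the EEG weight `α ∈ {0, 0.01, …, 1}` chosen by grid
search. Evaluation is stratified 10-fold cross-validation; by default all
data-dependent choices are nested inside training folds (a `paper` mode
reproduces post-hoc maximum-accuracy reporting).

## Worked example

```python
from neurofuse import (CVConfig, EEGSimConfig, FTCDSimConfig,
                       MultimodalFusion, build_filter_bank,
                       generate_paired_dataset)

pair = ("baseline", "left")
ds = generate_paired_dataset(
    EEGSimConfig(n_trials_per_class=12, n_channels=8, fs=128.0,
                 trial_len=3.0, snr_db=10.0, seed=42, classes=pair),
    FTCDSimConfig(n_trials_per_class=12, trial_len=1.5, seed=43,
                  classes=pair),
    pair,
)
cfg = CVConfig(n_folds=4, n_pairs_sweep=(1, 2), mode="paper", seed=0,
               bank=build_filter_bank(2.0, 30.0, 4, 7.0))
print(MultimodalFusion(ds, cfg).fit().summary())
```

prints

```
Multimodal EEG-fTCD fusion: cross-validated results
=====================================================
problem:            baseline-vs-left
trials:             24
folds:              4  (mode: paper, seed 0)
fused accuracy:     100.00 % +/- 0.00
EEG-only accuracy:  100.00 %
fTCD-only accuracy:  79.17 %
best alpha:         0.10   (EEG weight)
best n_pairs:       1
```

The simulated EEG carries a strong motor-imagery effect (contralaterally
suppressed mu/beta source power at 10 dB SNR), so the EEG stream alone
reaches 100% here and the fused accuracy is pinned at 100%. The Doppler
stream sees an 8 cm/s lateralized flow-velocity offset against 3 cm/s of
trial-to-trial baseline variability, giving 79% alone; because the EEG
evidence already decides every trial, the accuracy-versus-α curve is flat
from a small α upward and the grid search reports the smallest maximizer,
α = 0.10. On harder data (see
`neurofuse.validation.alpha_recovery_experiment`) α tracks the relative
informativeness of the two streams.

The same workflow is available from the shell:

```bash
neurofuse simulate -c config.yaml -o data/
neurofuse run      -c config.yaml -i data/ -o out/
neurofuse report   out*/report.json
```

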