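# eegclassify

A configurable, leakage-aware pipeline for two-class EEG epoch
classification, built for resting-state psychiatric-screening studies
(schizophrenia detection is the motivating use case) and for anyone who
needs to know how much of a reported EEG classification accuracy survives
subject-independent validation.

Scalp EEG studies segment each subject's recording into many short epochs.
Epochs from one subject are strongly correlated, so a random epoch-level
train/test split lets a classifier re-identify subjects instead of detecting
disease, inflating accuracy. This package provides the full pipeline —
synthetic cohorts, file I/O, preprocessing, tunable artifact removal,
multiscale features, feature selection, ensembles — together with validation
machinery that runs the *same* pipeline under epoch-level k-fold and under
leave-one-subject-out (LOSO) cross-validation and reports the gap.

## What is in the box

| Stage | Module | Core method |
|---|---|---|
| Synthetic cohorts | `eegclassify.synth` | band-limited oscillations over 1/f^k noise; class-dependent band effects (alpha ↓, theta ↑ in patients); log-normal per-subject gain; Poisson blink/EMG artifacts |
| I/O + preprocessing | `eegclassify.preprocess` | EDF and concatenated-text readers/writers, cohort manifests, zero-phase Butterworth bandpass (0.5–50 Hz), 6 s / 2 s-overlap epoching, per-epoch z-scoring |
| Artifact removal | `eegclassify.atar` | wavelet-packet decomposition with per-node robust thresholds θ = (β/0.1)·σ̂·√(2 ln n); aggressiveness parameter β (default 0.1) |
| Features | `eegclassify.features` | per channel: 13 time-domain (moments, RMS, SAD, Hjorth activity/mobility/complexity) + 8 spectral (δ/θ/α/β band powers, normalized spectral entropy, PSD moments) from Welch PSDs |
| Selection | `eegclassify.selection` | variance filter, plug-in mutual information I(X;Y) in bits, tree-based RFE, native greedy MRMR (argmax I(f;y) − mean I(f;s)), default panel k = 50 |
| Ensembles | `eegclassify.ensemble` | 10-family registry (RBF-SVM, KNN, gradient boosting, extra trees, …), randomized search tuned by stratified 5-fold CV inside the training fold, soft/hard voting, logistic-regression stacking |
| Evaluation | `eegclassify.evaluation` | random split / epoch k-fold / LOSO fold plans, audited leakage-free protocol execution, epoch- and subject-level metrics, percentile bootstrap CIs (B = 2000), threshold sweeps, Wilcoxon + Benjamini–Hochberg paired fold tests |

Subject-level predictions aggregate epoch probabilities: a subject's score
is its mean positive-class probability, thresholded at 0.5. Every fitting
stage inside `run_protocol` is recorded by a `FitAudit`, which proves that no
test row was ever consumed by a fit — the audited counterpart of the claim
that LOSO results are leakage-free.

## Worked example: the leakage gap

`examples/04_leakage_gap.py` builds a 10+10-subject cohort with a weak class
effect (alpha ×0.9, theta ×1.1 in patients) and a strong per-subject gain
(SD 0.5 on the log scale), then runs one identical KNN pipeline under both
validation schemes:

```
epoch-level accuracy: k-fold 0.830 vs LOSO 0.635
leakage gap (epoch level): +0.195
LOSO subject-level accuracy: 0.650, 95% bootstrap CI [45.0%, 85.0%]
```

The same features and the same classifier score 83% when epochs of a subject
can sit on both sides of the split, but only 63.5% on truly unseen subjects:
the 19.5-point difference is subject re-identification, not schizophrenia
detection. Disable the subject gain (`subject_effect_sd=0`) and the gap
collapses to zero — that contrast is asserted in the test suite.

`examples/05_bootstrap_ci.py` shows the uncertainty attached to small-cohort
subject-level accuracies:

```
subject-level accuracy: 82.14% (23/28)
95% percentile bootstrap CI: [67.86%, 96.43%]  (B = 2000)
larger cohort, 65/84 = 77.38%: CI [67.86%, 85.71%]
```

The other example scripts demonstrate cohort simulation (planted band-power
ratios recovered by Welch band powers), β-tunable artifact removal against a
known-clean reference, and MRMR panel selection.

## Command-line interface

The library is the primary surface; a thin CLI wires it to YAML run
configurations:

```bash
eegclassify simulate --config run.yaml        # cohort files + manifest
eegclassify features --config run.yaml        # cohort -> feature table CSV
eegclassify evaluate --config run.yaml        # feature table -> JSON reports
eegclassify leakage-report --config run.yaml  # k-fold vs LOSO comparison
```

All keys and their defaults live in `eegclassify.config.DEFAULT_CONFIG`;
every report embeds a provenance block (config hash, seed, version).

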