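# Methods

This note documents the models, numerical choices and limitations behind
`eegclassify`, in the order the pipeline runs.

## Synthetic cohort model

Each subject's recording is, per channel,

    x(t) = Σ_band  A_band · m_band(class) · g_subject · s_band(t)  +  σ_n · n(t)

where `s_band` is unit-RMS Gaussian noise band-limited to the canonical band
(4th-order Butterworth; narrowband noise rather than pure sines so PSDs have
realistic width), `n(t)` is unit-RMS 1/f^k noise shaped in the frequency
domain, `A_band` are RMS amplitudes in µV, `m_band` are the patient-class
multipliers, and `g_subject = exp(N(0, subject_effect_sd))` is a single
log-normal gain drawn once per subject and applied to all bands and
channels.

Defaults emulate a resting-state adolescent-cohort geometry: 14 + 14
subjects, 16 channels (10–20 names F7…O2), 128 Hz, 60 s (7680 samples per
channel), amplitudes δ/θ/α/β = 15/10/20/5 µV, patient multipliers θ ×1.3 and
α ×0.7 (the elevated-theta / reduced-alpha resting-state pattern),
`subject_effect_sd` 0.3, 1/f exponent 1, noise floor 8 µV RMS. The parameter
set mirrors the published field's amplitude scales; the `noise_amplitude`
field exists because the background level controls the SNR of the planted
band effects and must be explicit.

The per-subject gain is deliberately one-dimensional: it is the single knob
that makes epochs of one subject mutually informative, which is exactly what
epoch-level cross-validation can exploit and LOSO cannot. What the generator
does **not** model: dipole/head geometry (channels are exchangeable apart
from blink targeting), ERP structure, non-stationarity within a recording,
per-band subject effects, realistic artifact morphology beyond smooth ~100 µV
sub-5 Hz frontal blinks and >20 Hz Hann-windowed EMG bursts with Poisson
event times. Consequently, tests passing on synthetic cohorts demonstrate
the *machinery* (effect recovery, leakage quantification, calibration of the
bootstrap) — not clinical performance on real EEG.

## Preprocessing

Bandpass: Butterworth applied forward–backward (`sosfiltfilt`, zero phase).
The order defaults to 5: after the two passes this leaves ≤ 7% of mains
power (60 Hz at fs 250) while order 4 would leave 11%, above the 10% bound
the package's own stopband test requires. Epoching uses
`L = round(epoch_len·fs)` samples with hop `S = round((epoch_len−overlap)·fs)`,
0-based half-open windows, trailing partial windows dropped, giving
`floor((N−L)/S)+1` epochs; defaults 6 s / 2 s overlap. Epoch counts reported
for the public datasets this layout mimics are not mutually consistent under
any single convention, so both parameters stay configurable and no total is
hard-coded. A recording shorter than one window yields an empty epoch set
with a warning rather than an error, so cohort loops degrade gracefully.
Z-scoring (per epoch, per channel) is optional and off by default; constant
channels are left unchanged so the operation is total and idempotent.

EDF reading goes through MNE; writing uses a minimal built-in 16-bit EDF
writer (1-s records, symmetric physical range re-parsed from the formatted
header field so writer and reader agree exactly; quantization error ≤ half
of 2·range/(2¹⁶−2)). The concatenated-text format (all samples of channel 1,
then channel 2, …) round-trips losslessly. Class labels travel in a
`subject_id,label,path` manifest because neither signal format stores them
reliably.

## Artifact removal (ATAR-style)

Each processing window (per epoch, or 6-s windows of a continuous recording)
is decomposed with a full wavelet-packet tree (default `db4`, depth 5,
automatically capped at `dwt_max_level` with a logged warning;
periodization boundary mode keeps the transform orthogonal so coefficient
shrinkage can never add energy). Per terminal node, a robust scale
`σ̂ = IQR/1.349` gives the threshold

    θ = (β / 0.1) · σ̂ · √(2 ln n_node)

so the default β = 0.1 applies the plain universal threshold, smaller β is
more aggressive and β ≥ 2 leaves clean signals essentially untouched. Nodes
with `σ̂ = 0` are left unchanged (covers silence and pure DC). Three
attenuation modes act on super-threshold magnitudes: `soft` caps at θ,
`elastic` (default) maps |c| to θ·(1 + 0.2·ln(|c|/θ)) — a near-cap that
preserves super-threshold ordering; the slope 0.2 keeps a second pass
within 10% of the first pass's change while still suppressing blink
coefficients hard — and `linear-attenuate` ramps to zero at 2θ. All modes
shrink magnitudes pointwise, which yields the energy and β-monotonicity
guarantees the test suite asserts. Validation is by property (monotonicity,
energy, preservation of clean signals, artifact-variance reduction against
the generator's clean reference), not by numeric agreement with any
particular published implementation. ICA is intentionally not implemented;
`clean_epochs(..., method="hook")` accepts an external cleaner for
comparisons.

## Features

21 features per channel per epoch. Time domain (13): mean, variance, SD,
peak-to-peak, min, max, RMS, sum of absolute successive differences,
Fisher–Pearson skewness, excess kurtosis, and the Hjorth parameters —
activity = var(x), mobility = √(var(Δx)/var(x)), complexity =
mobility(Δx)/mobility(x). Constant signals map to mobility = complexity =
skewness = kurtosis = 0 rather than NaN so downstream selection never sees
missing values. Frequency domain (8): band powers (trapezoidal PSD integral)
over δ 0.5–4, θ 4–8, α 8–13, β 13–30 Hz (the δ lower edge is a canonical
choice; all edges configurable), spectral entropy, and the mean/skewness/
kurtosis of the PSD values on the 0.5–50 Hz grid. PSDs come from Welch's
method, defaults Hann window, 1-s segments, 50% overlap, per-segment
constant detrend — ≥ 5 averaged segments per 6-s epoch at 1 Hz resolution.
Spectral entropy is Shannon entropy (base 2) of the PSD normalized to sum 1
over 0.5–50 Hz, divided by log₂(#bins): 0 for a spectral line, 1 for a flat
spectrum, and 0 by convention at zero total power. Column names are
`CHANNEL__FEATURE`, channel-major, deterministic.

Wavelet-coefficient and fractal-dimension features are deliberately out of
scope: the extraction stage covers time-domain statistics and PSD-derived
features only.

## Feature selection

Mutual information uses a deterministic plug-in estimator: equal-frequency
discretization into 10 bins (quantile edges computed on the supplied —
always training — rows) and MI in bits from the empirical joint
distribution. This makes MI exactly invariant under strictly monotone
feature transforms and keeps the MRMR criterion reproducible across
platforms; the kNN-based estimators in common libraries are used only as
sanity cross-checks in tests. MRMR is the greedy MID (difference) variant:
seed with argmax I(f;y), then repeatedly add argmax
`I(f;y) − mean_{s∈S} I(f;s)`, ties broken by ascending feature name. RFE
drops the lowest-importance 10% (≥ 1) of features per round using extra-trees
importances until `n_keep` remain. The default chain is variance filter
(τ = 1e-10) then MRMR with k = 50. All selectors are fitted inside the
training fold by the evaluation engine.

## Ensembles

Classifier internals are scikit-learn's; this package owns the orchestration.
Scale-sensitive families (RBF-SVM, KNN, logistic regression, MLP) are
pipelined behind a `StandardScaler` fitted on training rows; tree models see
raw features. RBF-SVM probabilities come from `CalibratedClassifierCV`
(sigmoid calibration on internal training-fold splits), which soft voting
requires. Randomized search draws `n_iter` (default 25) candidates from the
family's documented search space — exhaustively when the space is smaller —
scored by stratified 5-fold accuracy on the training rows, ties keeping the
earlier candidate, then refits the winner on all training rows. Soft voting
is the weighted arithmetic mean of member probability rows, renormalized;
hard voting is weighted plurality with ties broken by summed member
probabilities, then by the positive class. Stacking builds meta-features by
5-fold cross-fitting the tuned members inside the training rows and fits a
logistic-regression meta-learner; members are then kept refit on all
training rows. Default membership: svm_rbf, knn, gradient_boosting,
extra_trees under soft voting.

## Evaluation protocol

Fold plans: `random_split` (single stratified epoch-level split, test
fraction 0.5), `kfold_epoch` (stratified epoch-level partition), `loso`
(one fold per subject; the plan validator enforces that each test set is
exactly one subject's epochs and every subject appears exactly once).
`run_protocol` executes selection → tuning → ensemble per fold on training
rows only, records every fitted row set in a `FitAudit`, asserts
train/test disjointness, pools held-out predictions, and computes epoch
metrics, subject metrics (mean-probability aggregation, threshold 0.5, ties
positive; majority voting is available as an option but mean probability is
deterministic under ties and uses calibration information), a
subject-resampled percentile bootstrap CI (B = 2000 default), and a
threshold sweep (grid step 0.001; smallest threshold attaining max F1).
ROC–AUC is computed once on the pooled cross-fold probabilities rather than
averaged per fold. The positive class is the patient group; control recall
is the specificity. Paired scheme/model comparisons use two-sided Wilcoxon
signed-rank tests on per-fold accuracies (zero differences discarded;
all-zero difference vectors report p = 1 with a warning) with
Benjamini–Hochberg adjustment across the comparison family. Per-fold
randomness derives from the run seed plus the fold index; reports embed the
seed and a config hash.

`leakage_report` runs the identical pipeline under `kfold_epoch` and `loso`
and reports both reports plus the epoch- and subject-level accuracy gaps.

## Desk-scale study sizes

The test suite and examples run the leakage study on 20 subjects per class
(16 channels, 128 Hz, 60 s), with non-overlapping 6-s epochs, a weak class
effect (α ×0.9, θ ×1.1, 15 µV noise floor) and a 5-NN classifier over
variance-filtered features. These choices are the study design, not
shortcuts: non-overlapping epochs remove the shared-samples leak so the
subject-gain mechanism is isolated (with 2-s overlap the k-fold/LOSO gap
stays positive even at `subject_effect_sd = 0`, because adjacent epochs
literally share data); KNN is the classifier most able to exploit
same-subject neighbours, making it the sharpest probe of leakage; and
variance-only selection keeps the amplitude features that carry subject
identity, which class-relevance-driven MRMR would discard. Under this
design the measured epoch-level gap rises from ≈ 0 (gain SD 0) through
+0.09 (SD 0.25) to +0.13 (SD 0.5), and protocol tests with a strong class
effect and weak subject effect confirm LOSO epoch accuracy ≥ 0.8.

## Known limitations

* Channels are statistically exchangeable; no topographic structure beyond
  frontal blink targeting, so spatial features would be meaningless here.
* The plug-in MI estimator is biased upward at small n (≈ bins/n·ln2 bits);
  acceptable for ranking, not for reporting MI values.
* The EDF writer covers the subset of EDF needed for round-tripping
  synthetic cohorts (integer sampling rates, uniform channel rates).
* Bootstrap CIs resample subjects only; epoch-level CIs are not produced.
* Cross-dataset transfer (train on one cohort, test on another) is
  expressible via the config but carries no tested guarantees.
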