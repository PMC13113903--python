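"""Quantify the accuracy inflation caused by epoch-level cross-validation.

Runs one identical pipeline (variance filter + 5-nearest-neighbour
classifier) under two validation schemes on a cohort with per-subject random
gains: epoch-level 5-fold cross-validation, which lets epochs of one subject
appear on both sides of a split, and leave-one-subject-out (LOSO), which
never does.  The k-fold minus LOSO accuracy difference is the leakage gap —
the part of "performance" that is really subject re-identification.
"""

import eegclassify as eeg
from eegclassify.ensemble import EnsembleConfig, ModelSpec

params = eeg.SynthParams(
    n_control=10, n_patient=10, duration=60.0, seed=11,
    subject_effect_sd=0.5, noise_amplitude=15.0,
    patient_multipliers={"delta": 1.0, "theta": 1.1, "alpha": 0.9,
                         "beta": 1.0})
cohort = eeg.gen_cohort(params)
epochs = eeg.segment_cohort([eeg.bandpass(r) for r in cohort],
                            epoch_len=6.0, overlap=0.0)
fm = eeg.build_feature_matrix(epochs)

cfg = EnsembleConfig(members=[ModelSpec("knn",
                                        search_space={"n_neighbors": [5]})])
report = eeg.leakage_report(fm, {"chain": ["variance"]}, cfg, k=5, seed=0,
                            bootstrap_B=500)
kf, loso = report["kfold"], report["loso"]
print(f"epoch-level accuracy: k-fold {kf.epoch_accuracy:.3f} "
      f"vs LOSO {loso.epoch_accuracy:.3f}")
print(f"leakage gap (epoch level): {report['epoch_accuracy_gap']:+.3f}")
print(f"LOSO subject-level accuracy: {loso.subject_accuracy:.3f}, "
      f"95% bootstrap CI [{loso.bootstrap['lower_pct']:.1f}%, "
      f"{loso.bootstrap['upper_pct']:.1f}%]")
print("a positive gap means epoch-level k-fold overstates how well the "
      "model generalizes to unseen subjects")
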