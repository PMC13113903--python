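"""Validation schemes, leakage-free protocol execution and reporting.

The engine runs the selection → tuning → ensemble pipeline inside each
training fold only, pools held-out predictions across folds, and reports
epoch-level and subject-level metrics with percentile-bootstrap confidence
intervals, a decision-threshold sweep, and paired Wilcoxon tests with
Benjamini–Hochberg correction.  A fit audit records the row set consumed by
every fitting stage and proves train/test disjointness — the machinery that
quantifies how much epoch-level k-fold validation leaks subject identity
relative to leave-one-subject-out (LOSO) validation.

The positive class is the patient group throughout; control recall is the
model's specificity.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import scipy.stats
from sklearn.metrics import confusion_matrix as sk_confusion
from sklearn.metrics import precision_recall_fscore_support, roc_auc_score
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit
from statsmodels.stats.multitest import multipletests

from .containers import CONTROL, PATIENT, FeatureMatrix
from .ensemble import EnsembleConfig, EnsembleModel
from .selection import apply_chain

__all__ = [
    "FoldPlan", "EvalReport", "LeakageError", "FitAudit",
    "make_folds", "run_protocol", "aggregate_subjects",
    "classification_metrics", "bootstrap_ci", "threshold_sweep",
    "paired_fold_test", "bh_adjust", "leakage_report",
]


class LeakageError(RuntimeError):
    """A fitting stage touched rows outside its training fold."""


@dataclass
class FoldPlan:
    """Named validation scheme with explicit train/test index pairs."""

    scheme: str
    folds: list[tuple[np.ndarray, np.ndarray]]
    params: dict
    seed: int

    def validate(self, subject_ids: list[str] | None = None) -> None:
        """Check the defining invariants of the scheme."""
        for i, (tr, te) in enumerate(self.folds):
            if np.intersect1d(tr, te).size:
                raise LeakageError(
                    f"fold {i}: train and test indices overlap")
        if self.scheme == "loso":
            if subject_ids is None:
                raise ValueError("loso validation needs subject_ids")
            sids = np.asarray(subject_ids)
            seen = []
            for i, (tr, te) in enumerate(self.folds):
                test_subjects = set(sids[te])
                if len(test_subjects) != 1:
                    raise LeakageError(
                        f"fold {i}: LOSO test set spans {test_subjects}")
                s = test_subjects.pop()
                if s in set(sids[tr]):
                    raise LeakageError(
                        f"fold {i}: subject {s} on both sides")
                seen.append(s)
            if sorted(seen) != sorted(set(sids)):
                raise LeakageError("LOSO folds do not cover every subject "
                                   "exactly once")
        if self.scheme == "kfold_epoch":
            pooled = np.sort(np.concatenate([te for _, te in self.folds]))
            n = max(int(np.max(pooled)) + 1, len(pooled))
            if not np.array_equal(pooled, np.arange(len(pooled))) or \
                    len(pooled) != n:
                raise LeakageError("k-fold test sets do not partition rows")


@dataclass
class EvalReport:
    """Pooled cross-fold evaluation results."""

    scheme: str
    fold_accuracies: list[float]
    y_true: list[int]
    y_pred: list[int]
    probs: list[float]
    subject_ids: list[str]
    epoch_metrics: dict
    subject_metrics: dict
    bootstrap: dict
    threshold_curve: dict
    chosen_params: list
    seed: int
    paired_tests: dict | None = None

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, default=str))

    @property
    def epoch_accuracy(self) -> float:
        return self.epoch_metrics["accuracy"]

    @property
    def subject_accuracy(self) -> float:
        return self.subject_metrics["accuracy"]


class FitAudit:
    """Records the global row indices consumed by every fitting stage."""

    def __init__(self) -> None:
        self.records: list[tuple[str, int, np.ndarray]] = []

    def record(self, stage: str, fold: int, rows: np.ndarray) -> None:
        self.records.append((stage, fold, np.asarray(rows)))

    def assert_no_leakage(self, plan: FoldPlan) -> None:
        """Every recorded fit must stay within its fold's training rows."""
        for stage, fold, rows in self.records:
            train = set(plan.folds[fold][0].tolist())
            extra = set(np.asarray(rows).tolist()) - train
            if extra:
                raise LeakageError(
                    f"stage {stage!r} of fold {fold} consumed non-training "
                    f"rows {sorted(extra)[:5]}...")


def make_folds(scheme: str, subject_ids: list[str], params: dict | None = None,
               seed: int = 0, labels: list[str] | None = None) -> FoldPlan:
    """Build a fold plan: ``random_split``, ``kfold_epoch`` or ``loso``.

    ``random_split`` is a single stratified epoch-level split (test fraction
    default 0.5, the conventional comparison split); ``kfold_epoch`` is a
    stratified epoch-level partition; ``loso`` holds out all epochs of one
    subject per fold.
    """
    params = dict(params or {})
    n = len(subject_ids)
    idx = np.arange(n)
    if scheme == "loso":
        subjects = sorted(set(subject_ids))
        if len(subjects) < 2:
            raise ValueError("loso requires at least 2 subjects")
        sids = np.asarray(subject_ids)
        folds = [(idx[sids != s], idx[sids == s]) for s in subjects]
    elif scheme == "kfold_epoch":
        k = int(params.get("k", 5))
        if k > n:
            raise ValueError(f"k={k} exceeds {n} epochs")
        if labels is None:
            raise ValueError("kfold_epoch needs labels for stratification")
        cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        folds = [(tr, te) for tr, te in cv.split(idx, np.asarray(labels))]
    elif scheme == "random_split":
        test_frac = float(params.get("test_frac", 0.5))
        if labels is None:
            raise ValueError("random_split needs labels for stratification")
        cv = StratifiedShuffleSplit(n_splits=1, test_size=test_frac,
                                    random_state=seed)
        folds = [next(iter(cv.split(idx, np.asarray(labels))))]
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    plan = FoldPlan(scheme, folds, params, seed)
    plan.validate(subject_ids if scheme == "loso" else None)
    return plan


def classification_metrics(y_true, y_pred, probs=None,
                           class_names=(CONTROL, PATIENT)) -> dict:
    """Accuracy, per-class and averaged precision/recall/F1, confusion
    matrix, and ROC–AUC (omitted when probabilities are absent).

    ``y_true``/``y_pred`` are 0/1 with 1 the positive (patient) class;
    ``probs`` are positive-class probabilities.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    prec, rec, f1, support = precision_recall_fscore_support(
        y_true, y_pred, labels=[0, 1], zero_division=0)
    out = {
        "accuracy": float(np.mean(y_true == y_pred)),
        "per_class": {
            class_names[c]: {
                "precision": float(prec[c]), "recall": float(rec[c]),
                "f1": float(f1[c]), "support": int(support[c])}
            for c in (0, 1)},
        "macro": {"precision": float(prec.mean()), "recall": float(rec.mean()),
                  "f1": float(f1.mean())},
        "weighted": {
            "precision": float(np.average(prec, weights=support)),
            "recall": float(np.average(rec, weights=support)),
            "f1": float(np.average(f1, weights=support))},
        "confusion_matrix": sk_confusion(y_true, y_pred,
                                         labels=[0, 1]).tolist(),
    }
    if probs is not None and len(np.unique(y_true)) == 2:
        out["roc_auc"] = float(roc_auc_score(y_true, np.asarray(probs)))
    return out


def aggregate_subjects(probs, subject_ids, y_true=None,
                       threshold: float = 0.5) -> dict:
    """Subject-level predictions from pooled epoch probabilities.

    A subject's score is the mean positive-class probability of its epochs;
    the subject is predicted positive iff score >= threshold (ties go to the
    positive class).  Returns per-subject score/prediction and, when truth is
    supplied, per-subject correctness.
    """
    probs = np.asarray(probs, float)
    sids = np.asarray(subject_ids)
    subjects = sorted(set(subject_ids))
    out = {}
    for s in subjects:
        mask = sids == s
        score = float(probs[mask].mean())
        pred = int(score >= threshold)
        entry = {"score": score, "pred": pred}
        if y_true is not None:
            truth = np.asarray(y_true)[mask]
            entry["true"] = int(truth[0])
            entry["correct"] = int(entry["true"] == pred)
        out[s] = entry
    return out


def bootstrap_ci(outcomes, B: int = 2000, level: float = 0.95,
                 seed: int = 0) -> tuple[float, float]:
    """Percentile bootstrap CI (in percent) for a mean of binary outcomes.

    Resamples the n outcomes with replacement B times and returns the
    (1-level)/2 and 1-(1-level)/2 percentiles of the resampled mean, on the
    0–100 scale.  With n subjects the bounds are quantized to multiples of
    100/n.
    """
    outcomes = np.asarray(outcomes, float)
    n = outcomes.size
    if n < 2:
        raise ValueError("bootstrap_ci needs at least 2 outcomes")
    rng = np.random.default_rng(seed)
    samples = rng.integers(0, n, size=(B, n))
    means = outcomes[samples].mean(axis=1) * 100.0
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(means, [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)


def threshold_sweep(probs, y_true, step: float = 0.001) -> dict:
    """Precision/recall/F1 of the positive class over a threshold grid.

    Returns the full curve and the smallest threshold attaining the maximum
    F1 (the documented tie rule).  Requires both classes in ``y_true``.
    """
    probs = np.asarray(probs, float)
    y_true = np.asarray(y_true)
    if len(np.unique(y_true)) < 2:
        raise ValueError("threshold_sweep requires both classes present")
    grid = np.arange(0.0, 1.0 + step / 2, step)
    pos = y_true == 1
    n_pos = pos.sum()
    pred = probs[None, :] >= grid[:, None]          # (n_thresh, n)
    tp = (pred & pos[None, :]).sum(axis=1).astype(float)
    fp = (pred & ~pos[None, :]).sum(axis=1).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = tp / n_pos
        f1 = np.where(precision + recall > 0,
                      2 * precision * recall / (precision + recall), 0.0)
    best = int(np.argmax(f1 > f1.max() - 1e-12))  # smallest argmax threshold
    return {
        "thresholds": grid.tolist(), "precision": precision.tolist(),
        "recall": recall.tolist(), "f1": f1.tolist(),
        "best_threshold": float(grid[best]), "best_f1": float(f1[best]),
    }


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(pvalues, float), method="fdr_bh")[1]


def paired_fold_test(comparisons: dict[str, tuple]) -> dict:
    """Two-sided Wilcoxon signed-rank tests over paired fold accuracies.

    ``comparisons`` maps a name to a pair of aligned per-fold accuracy
    vectors.  Zero differences are discarded (Wilcoxon convention); a
    comparison whose differences are all zero reports p = 1 with a warning.
    BH adjustment is applied across the whole family.
    """
    stats, raw_p = {}, []
    names = list(comparisons)
    for name in names:
        a, b = (np.asarray(v, float) for v in comparisons[name])
        if a.shape != b.shape:
            raise ValueError(f"{name}: fold vectors are not aligned")
        diff = a - b
        if np.all(diff == 0):
            warnings.warn(f"{name}: all paired differences are zero; p = 1")
            stats[name] = {"W": 0.0, "p": 1.0}
            raw_p.append(1.0)
            continue
        res = scipy.stats.wilcoxon(a, b, zero_method="wilcox",
                                   alternative="two-sided")
        stats[name] = {"W": float(res.statistic), "p": float(res.pvalue)}
        raw_p.append(float(res.pvalue))
    adj = bh_adjust(raw_p)
    for name, q in zip(names, adj):
        stats[name]["p_bh"] = float(q)
    return stats


def run_protocol(features: FeatureMatrix, plan: FoldPlan,
                 selection: dict | None = None,
                 ensemble: EnsembleConfig | None = None,
                 seed: int = 0, audit: FitAudit | None = None,
                 bootstrap_B: int = 2000,
                 threshold_step: float = 0.001) -> EvalReport:
    """Execute a leakage-free evaluation protocol over a fold plan.

    Per fold, the variance filter, the configured selector chain, feature
    standardization, hyperparameter tuning and the ensemble are all fitted on
    training rows only; test rows are only ever predicted.  Predictions are
    pooled across folds for epoch metrics, then aggregated per subject.
    All per-fold randomness derives from ``seed`` plus the fold index.
    """
    selection = dict(selection or {})
    ensemble = ensemble or EnsembleConfig()
    audit = audit or FitAudit()
    plan.validate(features.subject_ids if plan.scheme == "loso" else None)

    y = features.y()
    n = features.n_epochs
    pooled_pred = np.full(n, -1, dtype=int)
    pooled_prob = np.full(n, np.nan)
    covered = np.zeros(n, dtype=bool)
    fold_acc, chosen = [], []
    for f, (tr, te) in enumerate(plan.folds):
        if np.intersect1d(tr, te).size:
            raise LeakageError(f"fold {f}: train/test overlap")
        Xtr = features.rows(tr)
        ytr = y[tr]
        if len(np.unique(ytr)) < 2:
            raise ValueError(
                f"fold {f}: training set contains a single class")
        audit.record("selection", f, tr)
        sel = apply_chain(Xtr, ytr, chain=selection.get("chain"),
                          k=selection.get("k", 50),
                          tau=selection.get("tau", 1e-10),
                          seed=seed + f)
        cols = sel.selected
        fold_cfg = EnsembleConfig(
            members=ensemble.members, mode=ensemble.mode,
            weights=ensemble.weights,
            tuning={**ensemble.tuning,
                    "seed": ensemble.tuning.get("seed", 0) + seed + 100 * f})
        audit.record("ensemble_fit", f, tr)
        model = EnsembleModel(fold_cfg)
        model.fit(Xtr.select(cols).values, ytr)
        chosen.append(model.chosen_params_)
        Xte = features.rows(te).select(cols).values
        prob = model.predict_proba(Xte)[:, 1]
        pred = model.predict(Xte) if fold_cfg.mode == "vote_hard" else \
            (prob >= 0.5).astype(int)
        pooled_pred[te] = pred
        pooled_prob[te] = prob
        covered[te] = True
        fold_acc.append(float(np.mean(pred == y[te])))
    audit.assert_no_leakage(plan)

    mask = covered
    yt = y[mask]
    yp = pooled_pred[mask]
    pp = pooled_prob[mask]
    sids = [s for s, m in zip(features.subject_ids, mask) if m]
    epoch_metrics = classification_metrics(yt, yp, pp)
    subj = aggregate_subjects(pp, sids, y_true=yt)
    subj_outcomes = [v["correct"] for v in subj.values()]
    subj_true = np.array([v["true"] for v in subj.values()])
    subj_pred = np.array([v["pred"] for v in subj.values()])
    subject_metrics = classification_metrics(subj_true, subj_pred)
    subject_metrics["per_subject"] = subj
    lo, hi = bootstrap_ci(subj_outcomes, B=bootstrap_B, seed=seed)
    return EvalReport(
        scheme=plan.scheme,
        fold_accuracies=fold_acc,
        y_true=yt.tolist(), y_pred=yp.tolist(), probs=pp.tolist(),
        subject_ids=sids,
        epoch_metrics=epoch_metrics,
        subject_metrics=subject_metrics,
        bootstrap={"level": 0.95, "B": bootstrap_B, "seed": seed,
                   "lower_pct": lo, "upper_pct": hi},
        threshold_curve=threshold_sweep(pp, yt, step=threshold_step),
        chosen_params=chosen,
        seed=seed,
    )


def leakage_report(features: FeatureMatrix, selection: dict | None = None,
                   ensemble: EnsembleConfig | None = None, k: int = 5,
                   seed: int = 0, bootstrap_B: int = 2000) -> dict:
    """Run identical pipelines under epoch-level k-fold and LOSO and report
    the accuracy gap — the quantified cost of subject leakage."""
    labels = features.labels
    subjects_per_class = {
        lab: len({s for s, l in zip(features.subject_ids, labels) if l == lab})
        for lab in set(labels)}
    if any(v < 2 for v in subjects_per_class.values()):
        raise ValueError("leakage_report needs >= 2 subjects per class")
    plan_kf = make_folds("kfold_epoch", features.subject_ids, {"k": k},
                         seed=seed, labels=labels)
    plan_loso = make_folds("loso", features.subject_ids, seed=seed)
    rep_kf = run_protocol(features, plan_kf, selection, ensemble, seed=seed,
                          bootstrap_B=bootstrap_B)
    rep_loso = run_protocol(features, plan_loso, selection, ensemble,
                            seed=seed, bootstrap_B=bootstrap_B)
    return {
        "kfold": rep_kf,
        "loso": rep_loso,
        "epoch_accuracy_gap": rep_kf.epoch_accuracy - rep_loso.epoch_accuracy,
        "subject_accuracy_gap": (rep_kf.subject_accuracy
                                 - rep_loso.subject_accuracy),
    }
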