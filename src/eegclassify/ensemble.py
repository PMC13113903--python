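"""Classifier registry, randomized tuning, and voting/stacking combination.

Classifier internals are delegated to scikit-learn; this module owns the
search orchestration, the vote arithmetic and the stacking cross-fit
plumbing.  Scale-sensitive families (RBF-SVM, KNN, logistic regression, MLP)
are wrapped with a train-fold-fitted standardizer; tree models see raw
features.  The default ensemble membership is svm_rbf + knn +
gradient_boosting + extra_trees combined by soft voting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import clone
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import (AdaBoostClassifier, ExtraTreesClassifier,
                              GradientBoostingClassifier,
                              RandomForestClassifier)
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import (ParameterGrid, ParameterSampler,
                                     StratifiedKFold, cross_val_score)
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = ["ModelSpec", "EnsembleConfig", "FAMILIES", "DEFAULT_SEARCH_SPACES",
           "build_estimator", "tune_model", "soft_vote", "hard_vote",
           "EnsembleModel", "DEFAULT_MEMBERS"]

_SCALED = {"svm_rbf", "knn", "logistic_regression", "mlp"}

FAMILIES = ("svm_rbf", "knn", "gradient_boosting", "extra_trees",
            "random_forest", "decision_tree", "logistic_regression",
            "adaboost", "naive_bayes", "mlp")

DEFAULT_MEMBERS = ("svm_rbf", "knn", "gradient_boosting", "extra_trees")

DEFAULT_SEARCH_SPACES: dict[str, dict[str, list]] = {
    "svm_rbf": {"C": [0.1, 1, 10, 100],
                "gamma": ["scale", 0.001, 0.01, 0.1]},
    "knn": {"n_neighbors": [3, 5, 7, 11, 15]},
    "gradient_boosting": {"n_estimators": [100, 200],
                          "max_depth": [2, 3, 5],
                          "learning_rate": [0.05, 0.1]},
    "extra_trees": {"n_estimators": [100, 300, 500],
                    "max_depth": [None, 5, 10]},
    "random_forest": {"n_estimators": [100, 300, 500],
                      "max_depth": [None, 5, 10]},
    "decision_tree": {"max_depth": [None, 3, 5, 10],
                      "min_samples_leaf": [1, 5, 20]},
    "logistic_regression": {"C": [0.01, 0.1, 1, 10, 100]},
    "adaboost": {"n_estimators": [50, 100, 200],
                 "learning_rate": [0.5, 1.0]},
    "naive_bayes": {},
    "mlp": {"hidden_layer_sizes": [(50,), (100,), (50, 50)],
            "alpha": [1e-4, 1e-3, 1e-2]},
}


@dataclass
class ModelSpec:
    """One classifier family with its hyperparameter candidate sets."""

    family: str
    search_space: dict[str, list] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; "
                             f"choose from {FAMILIES}")
        if self.search_space is None:
            self.search_space = {k: list(v) for k, v in
                                 DEFAULT_SEARCH_SPACES[self.family].items()}


@dataclass
class EnsembleConfig:
    """Ensemble membership, combination mode and tuning budget."""

    members: list[ModelSpec] = field(default_factory=lambda: [
        ModelSpec(f) for f in DEFAULT_MEMBERS])
    mode: str = "vote_soft"
    weights: list[float] | None = None
    tuning: dict = field(default_factory=lambda: {
        "n_iter": 25, "folds": 5, "seed": 0})

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble needs at least one member")
        if self.mode not in ("vote_soft", "vote_hard", "stack"):
            raise ValueError(f"unknown ensemble mode {self.mode!r}")
        if self.weights is not None:
            if len(self.weights) != len(self.members):
                raise ValueError("weights length must match members")
            if any(w < 0 for w in self.weights):
                raise ValueError("weights must be nonnegative")


def build_estimator(family: str, params: dict | None = None, seed: int = 0):
    """Instantiate a (possibly scaler-wrapped) classifier."""
    params = params or {}
    if family == "svm_rbf":
        # probability outputs via internal calibration on training folds
        clf = CalibratedClassifierCV(
            SVC(kernel="rbf", random_state=seed, **params), ensemble=False)
    elif family == "knn":
        clf = KNeighborsClassifier(**params)
    elif family == "gradient_boosting":
        clf = GradientBoostingClassifier(random_state=seed, **params)
    elif family == "extra_trees":
        clf = ExtraTreesClassifier(random_state=seed, **params)
    elif family == "random_forest":
        clf = RandomForestClassifier(random_state=seed, **params)
    elif family == "decision_tree":
        clf = DecisionTreeClassifier(random_state=seed, **params)
    elif family == "logistic_regression":
        clf = LogisticRegression(max_iter=2000, random_state=seed, **params)
    elif family == "adaboost":
        clf = AdaBoostClassifier(random_state=seed, **params)
    elif family == "naive_bayes":
        clf = GaussianNB(**params)
    elif family == "mlp":
        clf = MLPClassifier(max_iter=500, random_state=seed, **params)
    else:
        raise ValueError(f"unknown family {family!r}")
    if family in _SCALED:
        return Pipeline([("scale", StandardScaler()), ("clf", clf)])
    return Pipeline([("clf", clf)])


def _n_candidates(space: dict[str, list]) -> int:
    n = 1
    for v in space.values():
        n *= len(v)
    return n


def tune_model(spec: ModelSpec, X: np.ndarray, y: np.ndarray,
               n_iter: int = 25, cv_folds: int = 5,
               seed: int | None = None):
    """Randomized search scored by stratified k-fold accuracy.

    Draws ``n_iter`` candidates from the spec's search space (exhaustive when
    the space is smaller), scores each by stratified ``cv_folds``-fold
    accuracy on the given rows, and refits the best on all given rows.
    Returns ``(fitted_pipeline, chosen_params)``; deterministic given seeds.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("tune_model requires both classes in y")
    seed = spec.seed if seed is None else seed
    space = spec.search_space or {}
    if not space or _n_candidates(space) == 1:
        candidates = [
            {k: v[0] for k, v in space.items()}] if space else [{}]
    elif _n_candidates(space) <= n_iter:
        candidates = list(ParameterGrid(space))
    else:
        candidates = list(ParameterSampler(space, n_iter=n_iter,
                                           random_state=seed))
    best_params, best_score = candidates[0], -np.inf
    if len(candidates) > 1:
        cv = StratifiedKFold(n_splits=cv_folds, shuffle=True,
                             random_state=seed)
        for cand in candidates:
            est = build_estimator(spec.family, cand, seed)
            score = cross_val_score(est, X, y, cv=cv,
                                    scoring="accuracy").mean()
            # strictly-better wins; ties keep the earlier candidate
            if score > best_score + 1e-12:
                best_score, best_params = score, cand
    model = build_estimator(spec.family, best_params, seed)
    model.fit(X, y)
    return model, best_params


def soft_vote(member_probs: list[np.ndarray],
              weights: list[float] | None = None) -> np.ndarray:
    """Weighted arithmetic mean of member probabilities, renormalized."""
    arrs = [np.asarray(p, dtype=float) for p in member_probs]
    shape = arrs[0].shape
    if any(a.shape != shape for a in arrs):
        raise ValueError("member probability arrays have mismatched shapes")
    w = np.ones(len(arrs)) if weights is None else np.asarray(weights, float)
    if w.shape[0] != len(arrs):
        raise ValueError("weights length must match member count")
    combined = np.tensordot(w, np.stack(arrs), axes=1) / w.sum()
    return combined / combined.sum(axis=1, keepdims=True)


def hard_vote(member_preds: list[np.ndarray],
              weights: list[float] | None = None,
              member_probs: list[np.ndarray] | None = None) -> np.ndarray:
    """Weighted plurality vote over binary labels.

    Ties are broken by the members' summed positive-class probabilities when
    available, then by the positive class.
    """
    preds = np.stack([np.asarray(p) for p in member_preds])  # (m, n)
    m, n = preds.shape
    w = np.ones(m) if weights is None else np.asarray(weights, float)
    pos_votes = np.tensordot(w, (preds == 1).astype(float), axes=1)
    neg_votes = w.sum() - pos_votes
    out = (pos_votes > neg_votes).astype(int)
    tie = np.isclose(pos_votes, neg_votes)
    if np.any(tie):
        if member_probs is not None:
            pos_prob = np.sum([np.asarray(p)[:, 1] for p in member_probs],
                              axis=0)
            out[tie] = (pos_prob[tie] * 2 >= m).astype(int)
        else:
            out[tie] = 1  # positive class by convention
    return out


class EnsembleModel:
    """Fitted ensemble: tuned members plus a combination rule.

    ``fit`` must be given training rows only; the evaluation engine enforces
    and audits this.  For ``stack`` mode, meta-features are 5-fold
    cross-fitted member probabilities and the meta-learner is logistic
    regression, after which members are refit on all rows.
    """

    def __init__(self, config: EnsembleConfig):
        self.config = config
        self.members_: list = []
        self.chosen_params_: list[dict] = []
        self.meta_: LogisticRegression | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "EnsembleModel":
        X = np.asarray(X)
        y = np.asarray(y)
        tuning = self.config.tuning
        n_iter = tuning.get("n_iter", 25)
        folds = tuning.get("folds", 5)
        seed = tuning.get("seed", 0)
        self.members_, self.chosen_params_ = [], []
        for i, spec in enumerate(self.config.members):
            model, params = tune_model(spec, X, y, n_iter=n_iter,
                                       cv_folds=folds, seed=seed + i)
            self.members_.append(model)
            self.chosen_params_.append(params)
        if self.config.mode == "stack":
            meta_X = self._cross_fit_meta(X, y, folds, seed)
            self.meta_ = LogisticRegression(max_iter=2000, random_state=seed)
            self.meta_.fit(meta_X, y)
            # members are already refit on all rows by tune_model
        return self

    def _cross_fit_meta(self, X: np.ndarray, y: np.ndarray, folds: int,
                        seed: int) -> np.ndarray:
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        meta = np.zeros((len(y), len(self.members_)))
        for tr, te in cv.split(X, y):
            for j, model in enumerate(self.members_):
                m = clone(model)
                m.fit(X[tr], y[tr])
                meta[te, j] = m.predict_proba(X[te])[:, 1]
        return meta

    def member_probs(self, X: np.ndarray) -> list[np.ndarray]:
        return [m.predict_proba(np.asarray(X)) for m in self.members_]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        probs = self.member_probs(X)
        if self.config.mode == "stack":
            meta_X = np.column_stack([p[:, 1] for p in probs])
            return self.meta_.predict_proba(meta_X)
        return soft_vote(probs, self.config.weights)

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.config.mode == "vote_hard":
            probs = self.member_probs(X)
            preds = [np.argmax(p, axis=1) for p in probs]
            return hard_vote(preds, self.config.weights, probs)
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)
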