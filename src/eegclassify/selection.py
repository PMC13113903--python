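"""Dimensionality reduction: variance filter, MI ranking, RFE and MRMR.

Mutual information uses a deterministic plug-in estimator: continuous
features are discretized into 10 equal-frequency bins and MI is computed in
bits from the empirical joint distribution.  MRMR is the greedy MID
(difference) variant: after seeding with the top-relevance feature, each step
picks ``argmax relevance(f) - mean MI(f, s) over selected s``, with ties
broken by ascending feature name for cross-platform determinism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.ensemble import ExtraTreesClassifier

from .containers import FeatureMatrix

__all__ = ["SelectionResult", "variance_filter", "mi_scores", "rfe_select",
           "mrmr_select", "apply_chain", "mutual_information_bits"]

DEFAULT_BINS = 10
DEFAULT_K = 50
DEFAULT_TAU = 1e-10


@dataclass
class SelectionResult:
    """Ordered feature panel with per-feature scores."""

    selected: list[str]
    scores: dict[str, float]
    method: str
    k: int

    def __post_init__(self) -> None:
        if len(set(self.selected)) != len(self.selected):
            raise ValueError("selected features contain duplicates")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "method": self.method, "k": self.k, "selected": self.selected,
            "scores": self.scores}, indent=1))

    @staticmethod
    def from_json(path) -> "SelectionResult":
        d = json.loads(Path(path).read_text())
        return SelectionResult(d["selected"], d["scores"], d["method"], d["k"])


def _discretize(x: np.ndarray, bins: int = DEFAULT_BINS) -> np.ndarray:
    """Equal-frequency binning into integer codes 0..bins-1."""
    edges = np.quantile(x, np.linspace(0, 1, bins + 1)[1:-1])
    return np.searchsorted(edges, x, side="right")


def _encode_labels(y) -> np.ndarray:
    y = np.asarray(y)
    _, codes = np.unique(y, return_inverse=True)
    return codes


def mutual_information_bits(cx: np.ndarray, cy: np.ndarray) -> float:
    """Plug-in MI in bits between two integer code vectors."""
    nx = int(cx.max()) + 1
    ny = int(cy.max()) + 1
    joint = np.bincount(cx * ny + cy, minlength=nx * ny).reshape(nx, ny)
    joint = joint / joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log2(joint / (px * py))
    return float(np.nansum(terms))


def variance_filter(X: FeatureMatrix, tau: float = DEFAULT_TAU) -> SelectionResult:
    """Keep features whose sample variance exceeds ``tau``."""
    if tau < 0:
        raise ValueError("tau must be >= 0")
    variances = X.values.var(axis=0)
    keep = [n for n, v in zip(X.feature_names, variances) if v > tau]
    return SelectionResult(keep,
                           dict(zip(X.feature_names, map(float, variances))),
                           "variance", len(keep))


def mi_scores(X: FeatureMatrix, y, bins: int = DEFAULT_BINS) -> dict[str, float]:
    """Per-feature mutual information (bits) with the class label."""
    cy = _encode_labels(y)
    if len(np.unique(cy)) < 2:
        raise ValueError("mi_scores requires at least 2 classes")
    return {
        name: mutual_information_bits(_discretize(X.values[:, j], bins), cy)
        for j, name in enumerate(X.feature_names)
    }


def rfe_select(X: FeatureMatrix, y, n_keep: int, seed: int = 0) -> SelectionResult:
    """Recursive feature elimination with tree-ensemble importances.

    Each round drops the lowest-importance 10% of remaining features (at
    least one) until ``n_keep`` remain.  Scores report the round at which a
    kept feature last survived (higher = retained longer is trivially true;
    kept features share the final round index, with final importances).
    """
    p = X.n_features
    if n_keep > p:
        raise ValueError(f"n_keep={n_keep} exceeds {p} features")
    y = np.asarray(y)
    remaining = list(range(p))
    importances = np.zeros(p)
    while len(remaining) > n_keep:
        est = ExtraTreesClassifier(n_estimators=100, random_state=seed)
        est.fit(X.values[:, remaining], y)
        imp = est.feature_importances_
        importances[remaining] = imp
        n_drop = max(1, int(0.1 * len(remaining)))
        n_drop = min(n_drop, len(remaining) - n_keep)
        order = np.argsort(imp, kind="stable")
        drop = {remaining[i] for i in order[:n_drop]}
        remaining = [j for j in remaining if j not in drop]
    est = ExtraTreesClassifier(n_estimators=100, random_state=seed)
    est.fit(X.values[:, remaining], y)
    importances[remaining] = est.feature_importances_
    names = [X.feature_names[j] for j in remaining]
    return SelectionResult(names,
                           {n: float(importances[X.feature_names.index(n)])
                            for n in names},
                           "rfe", n_keep)


def mrmr_select(X: FeatureMatrix, y, k: int = DEFAULT_K,
                bins: int = DEFAULT_BINS) -> SelectionResult:
    """Greedy minimum-redundancy maximum-relevance selection (MID variant).

    Returns features in selection order with the criterion value at the step
    each was picked (the first pick's score is its plain relevance).
    """
    p = X.n_features
    if k > p:
        raise ValueError(f"k={k} exceeds {p} features")
    cy = _encode_labels(y)
    if len(np.unique(cy)) < 2:
        raise ValueError("mrmr_select requires at least 2 classes")
    codes = np.column_stack([_discretize(X.values[:, j], bins)
                             for j in range(p)])
    relevance = np.array([mutual_information_bits(codes[:, j], cy)
                          for j in range(p)])
    names = X.feature_names

    def argbest(scores: np.ndarray, candidates: list[int]) -> int:
        top = max(scores[j] for j in candidates)
        tied = [j for j in candidates if scores[j] >= top - 1e-12]
        return min(tied, key=lambda j: names[j])

    candidates = list(range(p))
    first = argbest(relevance, candidates)
    selected = [first]
    picked_scores = {names[first]: float(relevance[first])}
    candidates.remove(first)
    red_sum = np.zeros(p)
    while len(selected) < k and candidates:
        last = selected[-1]
        for j in candidates:
            red_sum[j] += mutual_information_bits(codes[:, j],
                                                  codes[:, last])
        crit = relevance - red_sum / len(selected)
        pick = argbest(crit, candidates)
        selected.append(pick)
        picked_scores[names[pick]] = float(crit[pick])
        candidates.remove(pick)
    return SelectionResult([names[j] for j in selected], picked_scores,
                           "mrmr", k)


def apply_chain(X: FeatureMatrix, y, chain: list[str] | None = None,
                k: int = DEFAULT_K, tau: float = DEFAULT_TAU,
                seed: int = 0) -> SelectionResult:
    """Apply a selection chain (default ``variance`` then ``mrmr``).

    Every stage is fitted on the rows of ``X`` only — the evaluation engine
    passes training rows exclusively.
    """
    chain = chain if chain is not None else ["variance", "mrmr"]
    current = X
    result = SelectionResult(list(X.feature_names), {}, "identity",
                             X.n_features)
    for stage in chain:
        if stage == "variance":
            result = variance_filter(current, tau)
        elif stage == "mi":
            scores = mi_scores(current, y)
            order = sorted(scores, key=lambda n: (-scores[n], n))[:k]
            result = SelectionResult(order, scores, "mi", k)
        elif stage == "rfe":
            result = rfe_select(current, y, min(k, current.n_features), seed)
        elif stage == "mrmr":
            result = mrmr_select(current, y, min(k, current.n_features))
        else:
            raise ValueError(f"unknown selection stage {stage!r}")
        current = current.select(result.selected)
    return result
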