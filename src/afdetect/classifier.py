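"""Gaussian-kernel SVM training, cross-validation and exact binomial CIs.

Feature vectors are standardized (zero mean, unit variance, fitted on
training data only) before the RBF kernel, whose default width is
scikit-learn's ``gamma="scale"`` = 1 / (n_features * mean feature
variance).  The decision rule is the sign of the SVM decision function;
no operating threshold is tuned.  AF is the positive class throughout.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.model_selection import KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .rr_io import RhythmLabel

__all__ = [
    "ConfusionCounts",
    "CVReport",
    "BinomialCI",
    "TrainedClassifier",
    "train",
    "cross_validate",
    "confusion",
    "sensitivity",
    "specificity",
    "exact_binomial_ci",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion table with AF as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class BinomialCI:
    """Exact (Clopper-Pearson) binomial confidence interval."""

    successes: int
    trials: int
    level: float
    lower: float
    upper: float


@dataclass(frozen=True)
class CVReport:
    """Per-fold confusion counts and pooled metrics from k-fold CV."""

    k: int
    seed: int
    folds: tuple[ConfusionCounts, ...]
    aggregate: ConfusionCounts = field(init=False)

    def __post_init__(self) -> None:
        agg = ConfusionCounts(0, 0, 0, 0)
        for f in self.folds:
            agg = agg + f
        object.__setattr__(self, "aggregate", agg)

    @property
    def sensitivity(self) -> float:
        return sensitivity(self.aggregate)

    @property
    def specificity(self) -> float:
        return specificity(self.aggregate)

    def to_dict(self) -> dict:
        cc = self.aggregate
        return {
            "k": self.k,
            "seed": self.seed,
            "folds": [vars(f).copy() for f in self.folds],
            "aggregate": {"tp": cc.tp, "fp": cc.fp, "tn": cc.tn, "fn": cc.fn},
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


class TrainedClassifier:
    """A fitted standardize->RBF-SVM pipeline bound to a feature config.

    ``fingerprint`` identifies the feature pipeline the model was
    trained under; prediction refuses mismatched features when the
    caller passes its own fingerprint.
    """

    def __init__(self, pipeline: Pipeline, c: float, gamma,
                 fingerprint: str = ""):
        self._pipeline = pipeline
        self.c = c
        self.gamma = gamma
        self.fingerprint = fingerprint
        self.n_features = int(pipeline.named_steps["svm"].n_features_in_)

    def decision_scores(self, features: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(features, dtype=float))
        if x.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} features, got {x.shape[1]}"
            )
        return self._pipeline.decision_function(x)

    def predict(self, features: np.ndarray):
        """Label and signed decision score; AF iff score > 0."""
        scores = self.decision_scores(features)
        labels = [RhythmLabel.AF if s > 0 else RhythmLabel.NON_AF
                  for s in scores]
        if np.asarray(features).ndim == 1:
            return labels[0], float(scores[0])
        return labels, scores


def _as_binary(labels) -> np.ndarray:
    out = []
    for lb in labels:
        if isinstance(lb, RhythmLabel):
            out.append(1 if lb is RhythmLabel.AF else 0)
        elif isinstance(lb, str):
            out.append(1 if lb.upper() == "AF" else 0)
        else:
            out.append(int(bool(lb)))
    return np.asarray(out, dtype=int)


def train(
    features: np.ndarray,
    labels,
    c: float = 1.0,
    gamma="scale",
    seed: int = 0,
    fingerprint: str = "",
    class_weight=None,
) -> TrainedClassifier:
    """Fit the standardizer and Gaussian SVM on the given data.

    Both classes must be present.  ``gamma="scale"`` means
    1/(n_features * mean feature variance) of the standardized data.
    Deterministic given identical inputs and seed.
    """
    x = np.asarray(features, dtype=float)
    if x.ndim != 2:
        raise ValueError("features must be a 2D array (windows x features)")
    if not np.all(np.isfinite(x)):
        raise ValueError("features contain NaN or infinite values")
    y = _as_binary(labels)
    if y.size != x.shape[0]:
        raise ValueError("feature/label length mismatch")
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    pipe = Pipeline([
        ("scale", StandardScaler()),
        ("svm", SVC(C=c, kernel="rbf", gamma=gamma,
                    class_weight=class_weight, random_state=seed)),
    ])
    pipe.fit(x, y)
    return TrainedClassifier(pipe, c, gamma, fingerprint)


def cross_validate(
    features: np.ndarray,
    labels,
    k: int = 5,
    seed: int = 0,
    c: float = 1.0,
    gamma="scale",
    class_weight=None,
    groups=None,
) -> CVReport:
    """k-fold cross-validation with random fold assignment over items.

    Each fold validates a model trained (standardizer included) on the
    other k-1 folds; pooled confusion counts cover every item exactly
    once.  Pass ``groups`` (e.g. record ids) for a leakage-aware variant
    where whole groups are assigned to folds together.
    """
    if k < 2:
        raise ValueError("need at least 2 folds")
    x = np.asarray(features, dtype=float)
    y = _as_binary(labels)
    n = x.shape[0]
    if n < k:
        raise ValueError("need at least k items")
    if len(np.unique(y)) < 2:
        raise ValueError("cross-validation needs both classes")

    if groups is not None:
        fold_of = _group_folds(np.asarray(groups), k, seed)
        splits = [(np.flatnonzero(fold_of != i), np.flatnonzero(fold_of == i))
                  for i in range(k)]
    else:
        kf = KFold(n_splits=k, shuffle=True, random_state=seed)
        splits = list(kf.split(x))

    folds = []
    for tr, va in splits:
        model = train(x[tr], y[tr], c=c, gamma=gamma, seed=seed,
                      class_weight=class_weight)
        pred, _ = model.predict(x[va])
        truth = [RhythmLabel.AF if t else RhythmLabel.NON_AF for t in y[va]]
        folds.append(confusion(pred, truth))
    return CVReport(k=k, seed=seed, folds=tuple(folds))


def _group_folds(groups: np.ndarray, k: int, seed: int) -> np.ndarray:
    uniq = np.unique(groups)
    rng = np.random.default_rng(seed)
    order = rng.permutation(uniq.size)
    assign = {uniq[g]: i % k for i, g in enumerate(order)}
    return np.asarray([assign[g] for g in groups])


def confusion(predicted, truth) -> ConfusionCounts:
    """Count TP/FP/TN/FN with AF positive; inputs must align."""
    p = _as_binary(predicted)
    t = _as_binary(truth)
    if p.size != t.size:
        raise ValueError("prediction/truth length mismatch")
    return ConfusionCounts(
        tp=int(np.sum((p == 1) & (t == 1))),
        fp=int(np.sum((p == 1) & (t == 0))),
        tn=int(np.sum((p == 0) & (t == 0))),
        fn=int(np.sum((p == 0) & (t == 1))),
    )


def sensitivity(cc: ConfusionCounts) -> float:
    """TP / (TP + FN)."""
    if cc.tp + cc.fn == 0:
        raise ZeroDivisionError("no positive items: sensitivity undefined")
    return cc.tp / (cc.tp + cc.fn)


def specificity(cc: ConfusionCounts) -> float:
    """TN / (TN + FP)."""
    if cc.tn + cc.fp == 0:
        raise ZeroDivisionError("no negative items: specificity undefined")
    return cc.tn / (cc.tn + cc.fp)


def exact_binomial_ci(k: int, n: int, level: float = 0.95) -> BinomialCI:
    """Clopper-Pearson exact interval via beta quantiles.

    lower = BetaInv(a/2; k, n-k+1), upper = BetaInv(1-a/2; k+1, n-k),
    with lower = 0 at k = 0 and upper = 1 at k = n.
    """
    if n <= 0:
        raise ValueError("need at least one trial")
    if not 0 <= k <= n:
        raise ValueError("successes must lie in [0, n]")
    if not 0 < level < 1:
        raise ValueError("confidence level must be in (0, 1)")
    a = 1.0 - level
    lower = 0.0 if k == 0 else float(stats.beta.ppf(a / 2, k, n - k + 1))
    upper = 1.0 if k == n else float(stats.beta.ppf(1 - a / 2, k + 1, n - k))
    return BinomialCI(k, n, level, lower, upper)


def save_model(model: TrainedClassifier, path) -> None:
    """Write a single versioned model file (pickle payload)."""
    blob = {
        "format_version": MODEL_FORMAT_VERSION,
        "fingerprint": model.fingerprint,
        "c": model.c,
        "gamma": model.gamma,
        "pipeline": model._pipeline,
    }
    with open(path, "wb") as fh:
        pickle.dump(blob, fh, protocol=4)


def load_model(path) -> TrainedClassifier:
    with open(path, "rb") as fh:
        blob = pickle.load(fh)
    version = blob.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {version!r}")
    return TrainedClassifier(blob["pipeline"], blob["c"], blob["gamma"],
                             blob["fingerprint"])
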