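"""Information-gain feature ranking and the classifier cross-validation harness.

Feature value is measured by information gain,

.. math:: IG(\\mathrm{class}, x) = H(\\mathrm{class}) - H(\\mathrm{class} \\mid x),

with continuous features discretized by supervised entropy-based recursive
binary splitting under the Fayyad-Irani minimum-description-length (MDL)
stopping criterion.  A feature whose first candidate cut fails the MDL test
gets no bins and an information gain of 0; the "optimized profile" is the set
of features with strictly positive gain.

Cross-validation is stratified k-fold with all data-dependent steps
(per-feature z-scoring, information-gain selection) fitted inside the
training folds only, so no information leaks into the held-out folds.
Out-of-fold scores are pooled into a single ROC curve and a pooled confusion
matrix, from which the summary metrics are computed.

The five classifiers (logistic regression, Gaussian naive Bayes, AdaBoost
stumps, decision tree, random forest) are standard scikit-learn estimators;
entropy, information gain, discretization and every evaluation metric are
implemented in this package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.tree import DecisionTreeClassifier

from .metrics import (
    ConfusionMatrix,
    confusion_from_predictions,
    metrics_from_confusion,
    roc_curve,
)

__all__ = [
    "ALGORITHMS",
    "InformationGainResult",
    "ModelSpec",
    "FittedModel",
    "CVResult",
    "entropy",
    "mdl_cut_points",
    "information_gain",
    "rank_features",
    "optimized_profile",
    "train_model",
    "evaluate_independent",
    "cross_validate",
]


# ---------------------------------------------------------------------------
# Entropy / information gain with MDL discretization
# ---------------------------------------------------------------------------


def entropy(labels: Sequence) -> float:
    """Shannon entropy of a label sequence in bits; 0*log0 == 0."""
    arr = np.asarray(labels)
    if arr.size == 0:
        raise ValueError("entropy of an empty label sequence is undefined")
    _, counts = np.unique(arr, return_counts=True)
    p = counts / arr.size
    return float(-np.sum(p * np.log2(p)))


def _counts_entropy(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts[counts > 0] / n
    return float(-np.sum(p * np.log2(p)))


def _best_split(sorted_labels: np.ndarray, n_classes: int, boundaries: np.ndarray):
    """Best binary split position minimizing weighted class entropy.

    ``boundaries`` are the candidate split positions (index i splits into
    [:i], [i:]).  Returns (position, weighted_entropy, left_counts,
    right_counts) or None when no candidate exists.
    """
    n = sorted_labels.size
    onehot = np.zeros((n, n_classes), dtype=np.int64)
    onehot[np.arange(n), sorted_labels] = 1
    cum = np.cumsum(onehot, axis=0)
    total = cum[-1]

    best = None
    for i in boundaries:
        left = cum[i - 1]
        right = total - left
        w = (i / n) * _counts_entropy(left) + ((n - i) / n) * _counts_entropy(right)
        if best is None or w < best[1] - 1e-12:
            best = (int(i), w, left, right)
    return best


def _mdl_accept(
    n: int,
    parent_entropy: float,
    weighted_entropy: float,
    parent_counts: np.ndarray,
    left_counts: np.ndarray,
    right_counts: np.ndarray,
) -> bool:
    """Fayyad-Irani MDL criterion for accepting a binary split."""
    gain = parent_entropy - weighted_entropy
    k = int(np.count_nonzero(parent_counts))
    k1 = int(np.count_nonzero(left_counts))
    k2 = int(np.count_nonzero(right_counts))
    h_left = _counts_entropy(left_counts)
    h_right = _counts_entropy(right_counts)
    delta = math.log2(3**k - 2) - (
        k * parent_entropy - k1 * h_left - k2 * h_right
    )
    threshold = (math.log2(n - 1) + delta) / n
    return gain > threshold


def mdl_cut_points(values: Sequence[float], labels: Sequence[int]) -> tuple[float, ...]:
    """Supervised discretization cut points (entropy + MDL stopping).

    Returns the sorted cut points; empty when no split is justified.  Cuts
    are midpoints between adjacent distinct values, so the induced partition
    depends only on the ranks of ``values`` (invariant to strictly monotone
    transforms up to cut placement).
    """
    x = np.asarray(values, dtype=float)
    y_raw = np.asarray(labels)
    if x.size != y_raw.size:
        raise ValueError("values and labels must have equal length")
    classes, y = np.unique(y_raw, return_inverse=True)
    n_classes = classes.size

    order = np.argsort(x, kind="mergesort")
    xs, ys = x[order], y[order]
    cuts: list[float] = []

    def recurse(lo: int, hi: int) -> None:
        n = hi - lo
        if n < 2:
            return
        seg_x, seg_y = xs[lo:hi], ys[lo:hi]
        counts = np.bincount(seg_y, minlength=n_classes)
        parent_h = _counts_entropy(counts)
        if parent_h == 0.0:
            return
        boundaries = np.nonzero(np.diff(seg_x) != 0)[0] + 1
        if boundaries.size == 0:
            return
        best = _best_split(seg_y, n_classes, boundaries)
        pos, w, left_c, right_c = best
        if not _mdl_accept(n, parent_h, w, counts, left_c, right_c):
            return
        cuts.append(float((seg_x[pos - 1] + seg_x[pos]) / 2.0))
        recurse(lo, lo + pos)
        recurse(lo + pos, hi)

    recurse(0, x.size)
    return tuple(sorted(cuts))


@dataclass(frozen=True)
class InformationGainResult:
    """Gain (bits) of one feature with its accepted discretization cuts."""

    feature: str
    gain: float
    cut_points: tuple[float, ...] = ()


def information_gain(
    values: Sequence[float],
    labels: Sequence[int],
    cut_points: Optional[Sequence[float]] = None,
    feature: str = "",
) -> InformationGainResult:
    """IG = H(class) - sum_b (n_b / n) H(class | bin b) over MDL bins.

    When no cut point is accepted the gain is 0.  Constant labels are an
    error: with H(class) = 0 a ranking is meaningless.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    if x.size != y.size:
        raise ValueError("values and labels must have equal length")
    h_class = entropy(y)
    if h_class == 0.0:
        raise ValueError("labels are constant; information gain is undefined")
    cuts = tuple(cut_points) if cut_points is not None else mdl_cut_points(x, y)
    if not cuts:
        return InformationGainResult(feature=feature, gain=0.0, cut_points=())
    bins = np.searchsorted(np.asarray(cuts), x, side="left")
    cond = 0.0
    for b in np.unique(bins):
        mask = bins == b
        cond += (mask.sum() / x.size) * entropy(y[mask])
    return InformationGainResult(
        feature=feature, gain=max(0.0, h_class - cond), cut_points=cuts
    )


def rank_features(X: pd.DataFrame, labels: Sequence[int]) -> list[InformationGainResult]:
    """Rank all columns by information gain, descending.

    Ties (including the common all-zero-gain case) are broken by column
    order, which is fixed by the feature schema.
    """
    y = np.asarray(labels)
    if min(np.unique(y, return_counts=True)[1]) < 2:
        raise ValueError("need at least 2 samples per class to rank features")
    results = [
        information_gain(X[col].to_numpy(), y, feature=str(col)) for col in X.columns
    ]
    order = sorted(range(len(results)), key=lambda i: (-results[i].gain, i))
    return [results[i] for i in order]


def optimized_profile(ranking: Sequence[InformationGainResult]) -> list[str]:
    """The feature subset with strictly positive information gain."""
    return [r.feature for r in ranking if r.gain > 0.0]


# ---------------------------------------------------------------------------
# Classifiers
# ---------------------------------------------------------------------------

ALGORITHMS = (
    "logistic_regression",
    "naive_bayes",
    "adaboost",
    "decision_tree",
    "random_forest",
)

#: Short CLI aliases.
ALGORITHM_ALIASES = {
    "lr": "logistic_regression",
    "nb": "naive_bayes",
    "dt": "decision_tree",
    "rf": "random_forest",
    "adaboost": "adaboost",
}


@dataclass(frozen=True)
class ModelSpec:
    """Algorithm choice plus hyperparameters and seed, recorded in outputs."""

    algorithm: str = "random_forest"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        algo = ALGORITHM_ALIASES.get(self.algorithm, self.algorithm)
        object.__setattr__(self, "algorithm", algo)
        if algo not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}, got {algo!r}")

    def build(self):
        hp = dict(self.hyperparameters)
        if self.algorithm == "logistic_regression":
            hp.setdefault("max_iter", 2000)
            return LogisticRegression(random_state=self.seed, **hp)
        if self.algorithm == "naive_bayes":
            return GaussianNB(**hp)
        if self.algorithm == "adaboost":
            hp.setdefault("n_estimators", 50)  # depth-1 stumps by default
            return AdaBoostClassifier(random_state=self.seed, **hp)
        if self.algorithm == "decision_tree":
            hp.setdefault("criterion", "gini")
            return DecisionTreeClassifier(random_state=self.seed, **hp)
        hp.setdefault("n_estimators", 500)
        hp.setdefault("max_features", "sqrt")
        return RandomForestClassifier(random_state=self.seed, **hp)

    def to_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "hyperparameters": dict(self.hyperparameters),
            "seed": self.seed,
        }


class _Scaler:
    """Per-feature z-scoring with training-fold statistics."""

    def __init__(self, X: np.ndarray):
        self.mean = X.mean(axis=0)
        sd = X.std(axis=0)
        self.sd = np.where(sd > 0, sd, 1.0)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.sd


def _as_binary(labels: Sequence, positive_label) -> tuple[np.ndarray, object]:
    y_raw = np.asarray(labels)
    classes = np.unique(y_raw)
    if classes.size != 2:
        raise ValueError(f"need exactly 2 classes, got {classes.tolist()}")
    if positive_label is None:
        positive_label = "carrier" if "carrier" in classes.tolist() else classes.max()
    if positive_label not in classes:
        raise ValueError(f"positive label {positive_label!r} not in {classes.tolist()}")
    return (y_raw == positive_label).astype(int), positive_label


@dataclass
class FittedModel:
    """A trained classifier bundled with its preprocessing state."""

    spec: ModelSpec
    model: object
    scaler: _Scaler
    features: list[str]
    positive_label: object
    train_ids: tuple[str, ...] = ()

    def scores(self, X: pd.DataFrame) -> np.ndarray:
        Z = self.scaler.transform(X[self.features].to_numpy(dtype=float))
        proba = self.model.predict_proba(Z)
        pos_col = list(self.model.classes_).index(1)
        return proba[:, pos_col]


def train_model(
    X: pd.DataFrame,
    labels: Sequence,
    spec: ModelSpec,
    select: bool = True,
    positive_label=None,
) -> FittedModel:
    """Fit scaler, optional IG selection, and the classifier on all rows of X."""
    y, pos = _as_binary(labels, positive_label)
    scaler = _Scaler(X.to_numpy(dtype=float))
    features = list(map(str, X.columns))
    if select:
        ranking = rank_features(X, y)
        chosen = optimized_profile(ranking)
        if chosen:  # all-zero gains: fall back to the full profile
            features = chosen
    sub_scaler = _Scaler(X[features].to_numpy(dtype=float))
    model = spec.build()
    model.fit(sub_scaler.transform(X[features].to_numpy(dtype=float)), y)
    return FittedModel(
        spec=spec,
        model=model,
        scaler=sub_scaler,
        features=features,
        positive_label=pos,
        train_ids=tuple(map(str, X.index)),
    )


def evaluate_independent(
    fitted: FittedModel,
    X_test: pd.DataFrame,
    labels: Sequence,
    threshold: float = 0.5,
) -> dict:
    """Confusion-matrix metrics plus AUC on an independent held-out set.

    Any overlap between the training and test participant ids is an error.
    """
    overlap = set(fitted.train_ids) & set(map(str, X_test.index))
    if overlap:
        raise ValueError(f"test set overlaps training set: {sorted(overlap)}")
    y, _ = _as_binary(labels, fitted.positive_label)
    scores = fitted.scores(X_test)
    pred = (scores >= threshold).astype(int)
    cm = confusion_from_predictions(y, pred)
    out = metrics_from_confusion(cm)
    out["auc"] = roc_curve(scores, y).auc
    out["confusion"] = cm
    out["scores"] = scores
    return out


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------


@dataclass
class CVResult:
    """Result of a stratified k-fold run.

    ``fold_assignments`` maps each sample (row order of X) to its fold;
    ``oof_scores`` are the pooled out-of-fold carrier scores feeding the
    single ROC curve; ``summary`` holds the pooled-confusion metrics.
    """

    spec: ModelSpec
    k: int
    seed: int
    select: bool
    sample_ids: tuple[str, ...]
    fold_assignments: np.ndarray
    fold_confusions: list[ConfusionMatrix]
    fold_features: list[list[str]]
    fold_gains: list[list[InformationGainResult]]
    oof_scores: np.ndarray
    oof_predictions: np.ndarray
    pooled_confusion: ConfusionMatrix
    summary: dict[str, float]
    roc: object

    def mean_gains(self) -> pd.DataFrame:
        """Per-feature mean +/- SD of training-fold information gain."""
        if not self.fold_gains:
            return pd.DataFrame(columns=["mean_gain", "sd_gain"])
        per_fold = [
            {r.feature: r.gain for r in fold} for fold in self.fold_gains
        ]
        frame = pd.DataFrame(per_fold)
        out = pd.DataFrame(
            {"mean_gain": frame.mean(axis=0), "sd_gain": frame.std(axis=0, ddof=1)}
        )
        return out.sort_values("mean_gain", ascending=False)


def cross_validate(
    X: pd.DataFrame,
    labels: Sequence,
    spec: ModelSpec,
    k: int = 10,
    select: bool = True,
    seed: int = 0,
    positive_label=None,
    threshold: float = 0.5,
) -> CVResult:
    """Stratified k-fold cross-validation with in-fold feature selection.

    Per fold: z-score features with training-fold statistics, rank features
    by information gain on the training fold only (when ``select``), train
    the classifier, and score the held-out fold.  Pooled out-of-fold scores
    give a single ROC curve; summary metrics come from the pooled confusion
    counts at the given score threshold.
    """
    y, pos = _as_binary(labels, positive_label)
    n = len(y)
    if n < k:
        raise ValueError(f"need at least k={k} samples, got {n}")
    if min(np.bincount(y)) < k:
        raise ValueError("every training fold needs both classes; too few per class")

    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_assignments = np.full(n, -1, dtype=int)
    oof_scores = np.full(n, np.nan)
    oof_pred = np.full(n, -1, dtype=int)
    fold_confusions: list[ConfusionMatrix] = []
    fold_features: list[list[str]] = []
    fold_gains: list[list[InformationGainResult]] = []

    Xv = X.to_numpy(dtype=float)
    columns = list(map(str, X.columns))
    for fold, (train_idx, test_idx) in enumerate(splitter.split(Xv, y)):
        fold_assignments[test_idx] = fold
        X_train = pd.DataFrame(Xv[train_idx], columns=columns)
        y_train = y[train_idx]
        features = columns
        if select:
            ranking = rank_features(X_train, y_train)
            fold_gains.append(ranking)
            chosen = optimized_profile(ranking)
            if chosen:
                features = chosen
        fold_features.append(list(features))
        cols = [columns.index(f) for f in features]
        scaler = _Scaler(Xv[np.ix_(train_idx, cols)])
        model = spec.build()
        model.fit(scaler.transform(Xv[np.ix_(train_idx, cols)]), y_train)
        proba = model.predict_proba(scaler.transform(Xv[np.ix_(test_idx, cols)]))
        pos_col = list(model.classes_).index(1)
        scores = proba[:, pos_col]
        pred = (scores >= threshold).astype(int)
        oof_scores[test_idx] = scores
        oof_pred[test_idx] = pred
        fold_confusions.append(confusion_from_predictions(y[test_idx], pred))

    pooled = confusion_from_predictions(y, oof_pred)
    summary = metrics_from_confusion(pooled)
    roc = roc_curve(oof_scores, y)
    summary["auc"] = roc.auc
    return CVResult(
        spec=spec,
        k=k,
        seed=seed,
        select=select,
        sample_ids=tuple(map(str, X.index)),
        fold_assignments=fold_assignments,
        fold_confusions=fold_confusions,
        fold_features=fold_features,
        fold_gains=fold_gains,
        oof_scores=oof_scores,
        oof_predictions=oof_pred,
        pooled_confusion=pooled,
        summary=summary,
        roc=roc,
    )
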