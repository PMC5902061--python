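"""Classifier comparison under random and time-separated cross-validation.

Three classifiers are compared on the selected-channel feature matrices:
a small feed-forward network (one tanh hidden layer of 10 units, trained
with a quasi-Newton optimizer), a distance-weighted k-nearest-neighbour
vote (Euclidean metric, exhaustive search), and an RBF-kernel support
vector machine (libsvm's SMO-type solver).  All three emit a continuous
target-class score in [0, 1]; hard labels threshold the score at 0.5 and
the ROC sweeps all thresholds.

Two fold-assignment schemes are provided: the usual stratified random
k-fold, and a time-separated k-fold in which the trial of within-class
time rank r is tested in fold r mod k, so every test fold spans the whole
session and temporally adjacent trials land in different folds.  This
guards the accuracy estimate against slow session drift.  Normalization
(z-scoring) and channel selection are fit on the training fold only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .containers import EpochSet
from .features import FeatureMatrix, build_feature_matrix
from .montage import TARGET
from .selection import stepwise_select

__all__ = [
    "ClassifierSpec",
    "CVScheme",
    "EvaluationReport",
    "normalize_features",
    "fit_predict",
    "make_folds",
    "evaluate",
    "compare_classifiers",
]


@dataclass
class ClassifierSpec:
    """One of the three compared classifiers and its hyperparameters.

    ``kind`` is "mlp" (tanh hidden layer, default 10 units, quasi-Newton
    training), "knn" (odd k, Euclidean, distance-weighted vote) or "svm"
    (RBF kernel, penalty C, gamma defaulting to 1/n_features).
    """

    kind: str = "mlp"
    hidden_units: int = 10
    max_epochs: int = 500
    k: int = 5
    C: float = 1.0
    gamma: float | None = None  # None -> 1 / n_features
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("mlp", "knn", "svm"):
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        if self.k < 1 or self.k % 2 == 0:
            raise ValueError("k must be odd and >= 1")
        if self.C <= 0 or (self.gamma is not None and self.gamma <= 0):
            raise ValueError("C and gamma must be positive")


@dataclass
class CVScheme:
    """Cross-validation fold-assignment scheme."""

    kind: str = "random_kfold"
    n_folds: int = 10
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("random_kfold", "time_separated_kfold"):
            raise ValueError(f"unknown CV scheme {self.kind!r}")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


@dataclass
class EvaluationReport:
    """Sensitivity/specificity/accuracy plus the ROC curve and its AUC."""

    sensitivity: float
    specificity: float
    accuracy: float
    roc: np.ndarray = field(repr=False)  # (n_points, 2) of (FPR, TPR)
    auc: float = float("nan")
    n: int = 0


def _as_binary(labels: np.ndarray) -> np.ndarray:
    return np.asarray([1 if lab == TARGET else 0 for lab in labels])


def normalize_features(
    train: np.ndarray, apply_to: np.ndarray, channel_labels: list[str] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Column z-scores with mean/sd estimated on the training slice only.

    Returns the transformed (train, apply_to) pair; raises when a training
    column has zero variance, naming the column.
    """
    train = np.asarray(train, dtype=float)
    apply_to = np.asarray(apply_to, dtype=float)
    if train.shape[0] == 0:
        raise ValueError("empty training slice")
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        name = channel_labels[bad[0]] if channel_labels else f"column {bad[0]}"
        raise ValueError(f"zero variance in training column {name}")
    return (train - mean) / sd, (apply_to - mean) / sd


def fit_predict(
    spec: ClassifierSpec,
    train_x: np.ndarray,
    train_y: np.ndarray,
    test_x: np.ndarray,
) -> np.ndarray:
    """Train one classifier and score the test rows.

    ``train_y`` may be class-label strings or 0/1. The returned score in
    [0, 1] is the network output (mlp), the distance-weighted target vote
    fraction (knn), or the logistic-linked decision value (svm). Training
    is deterministic given ``spec.seed``.
    """
    train_x = np.asarray(train_x, dtype=float)
    test_x = np.asarray(test_x, dtype=float)
    y = np.asarray(train_y)
    if y.dtype.kind in "OUS":
        y = _as_binary(y)
    if np.unique(y).size < 2:
        raise ValueError("training labels contain a single class")
    if test_x.shape[1] != train_x.shape[1]:
        raise ValueError("train/test feature dimension mismatch")

    if spec.kind == "mlp":
        clf = MLPClassifier(
            hidden_layer_sizes=(spec.hidden_units,),
            activation="tanh",
            solver="lbfgs",
            max_iter=spec.max_epochs,
            random_state=spec.seed,
        )
        with warnings.catch_warnings():
            # max_epochs is a fixed training budget, not a convergence target
            warnings.simplefilter("ignore", ConvergenceWarning)
            clf.fit(train_x, y)
        return clf.predict_proba(test_x)[:, list(clf.classes_).index(1)]
    if spec.kind == "knn":
        clf = KNeighborsClassifier(
            n_neighbors=min(spec.k, len(y)),
            weights="distance",
            metric="euclidean",
            algorithm="brute",
        )
        clf.fit(train_x, y)
        return clf.predict_proba(test_x)[:, list(clf.classes_).index(1)]
    # svm
    gamma = spec.gamma if spec.gamma is not None else 1.0 / train_x.shape[1]
    clf = SVC(kernel="rbf", C=spec.C, gamma=gamma, random_state=spec.seed)
    clf.fit(train_x, y)
    decision = clf.decision_function(test_x)
    if list(clf.classes_) == [1, 0]:  # decision is for classes_[1]
        decision = -decision
    return 1.0 / (1.0 + np.exp(-decision))


def make_folds(
    labels: np.ndarray, time_index: np.ndarray, scheme: CVScheme
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Build (train_indices, test_indices) pairs for one CV scheme.

    random_kfold: stratified (optional) random partition seeded by the
    scheme. time_separated_kfold: the observation of time rank r (within
    its class when stratified) is tested in fold r mod n_folds, spreading
    each fold's test set over the whole session.
    """
    labels = np.asarray(labels)
    time_index = np.asarray(time_index)
    n = labels.size
    _, counts = np.unique(labels, return_counts=True)
    if scheme.n_folds > counts.min():
        raise ValueError(
            f"n_folds={scheme.n_folds} exceeds the smallest class size {counts.min()}"
        )
    if scheme.kind == "random_kfold":
        if scheme.stratified:
            splitter = StratifiedKFold(
                n_splits=scheme.n_folds, shuffle=True, random_state=scheme.seed
            )
            return [
                (tr, te) for tr, te in splitter.split(np.zeros((n, 1)), labels)
            ]
        rng = np.random.default_rng(scheme.seed)
        perm = rng.permutation(n)
        fold_of = np.empty(n, dtype=int)
        fold_of[perm] = np.arange(n) % scheme.n_folds
    else:  # time_separated_kfold
        fold_of = np.empty(n, dtype=int)
        if scheme.stratified:
            for lab in np.unique(labels):
                idx = np.flatnonzero(labels == lab)
                order = idx[np.argsort(time_index[idx], kind="stable")]
                fold_of[order] = np.arange(order.size) % scheme.n_folds
        else:
            order = np.argsort(time_index, kind="stable")
            fold_of[order] = np.arange(n) % scheme.n_folds
    all_idx = np.arange(n)
    return [
        (all_idx[fold_of != f], all_idx[fold_of == f])
        for f in range(scheme.n_folds)
    ]


def evaluate(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> EvaluationReport:
    """Confusion-matrix rates at the threshold plus the full ROC and AUC.

    Target is the positive class: sensitivity = TP/(TP+FN), specificity =
    TN/(TN+FP). The ROC sweeps every distinct score (plus sentinels) and
    the AUC is its trapezoid integral.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if y.dtype.kind in "OUS":
        y = _as_binary(y)
    if np.unique(y).size < 2:
        raise ValueError("labels contain a single class")
    pred = scores >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    fp = int(np.sum(pred & (y == 0)))
    fpr, tpr, _ = roc_curve(y, scores, drop_intermediate=False)
    roc = np.column_stack([fpr, tpr])
    auc = float(np.trapezoid(tpr, fpr))
    return EvaluationReport(
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        accuracy=(tp + tn) / y.size,
        roc=roc,
        auc=auc,
        n=int(y.size),
    )


def compare_classifiers(
    epochs: EpochSet,
    features: list[str],
    scheme: CVScheme,
    specs: list[ClassifierSpec],
    n_select: int = 3,
    feature_params: dict | None = None,
) -> tuple[pd.DataFrame, dict[tuple[str, str], EvaluationReport]]:
    """Full feature -> selection -> normalization -> fit -> evaluation loop.

    For each feature, channel selection and z-normalization are re-fit
    inside every training fold (no test-row leakage); per-fold
    sensitivity/specificity/accuracy are aggregated as mean, sd, and
    maximum, and one pooled ROC/AUC per (feature, classifier) is computed
    from the concatenated out-of-fold scores.

    Returns the aggregate table and a dict of pooled
    :class:`EvaluationReport` keyed by (feature, classifier kind).
    """
    feature_params = feature_params or {}
    rows = []
    pooled: dict[tuple[str, str], EvaluationReport] = {}
    for feat in features:
        fm = build_feature_matrix(epochs, feat, **feature_params.get(feat, {}))
        folds = make_folds(fm.class_labels, fm.time_index, scheme)
        per_fold: dict[str, list[EvaluationReport]] = {s.kind: [] for s in specs}
        oof: dict[str, tuple[list, list]] = {s.kind: ([], []) for s in specs}
        for train_idx, test_idx in folds:
            train_fm = FeatureMatrix(
                feature_name=fm.feature_name,
                values=fm.values[train_idx],
                channel_labels=fm.channel_labels,
                class_labels=fm.class_labels[train_idx],
                condition=fm.condition[train_idx],
                time_index=fm.time_index[train_idx],
            )
            sel = stepwise_select(train_fm, n_select=n_select)
            cols = [fm.channel_labels.index(c) for c in sel.ordered_channels]
            tr_x, te_x = normalize_features(
                fm.values[np.ix_(train_idx, cols)],
                fm.values[np.ix_(test_idx, cols)],
                channel_labels=sel.ordered_channels,
            )
            tr_y = fm.class_labels[train_idx]
            te_y = fm.class_labels[test_idx]
            for spec in specs:
                scores = fit_predict(spec, tr_x, tr_y, te_x)
                per_fold[spec.kind].append(evaluate(scores, te_y))
                oof[spec.kind][0].extend(scores)
                oof[spec.kind][1].extend(te_y)
        for spec in specs:
            reps = per_fold[spec.kind]
            pooled_rep = evaluate(
                np.array(oof[spec.kind][0]), np.array(oof[spec.kind][1], dtype=object)
            )
            pooled[(feat, spec.kind)] = pooled_rep
            row = {"feature": feat, "classifier": spec.kind, "auc": pooled_rep.auc}
            for metric in ("sensitivity", "specificity", "accuracy"):
                vals = np.array([getattr(r, metric) for r in reps])
                row[f"{metric}_mean"] = vals.mean()
                row[f"{metric}_sd"] = vals.std(ddof=1)
                row[f"{metric}_max"] = vals.max()
            rows.append(row)
    return pd.DataFrame(rows), pooled
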