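"""Response classification: K-NN and naive Bayes in a LOO-CV wrapper.

Binary CR-vs-PR prediction from delta features. Feature subsets are chosen
by sequential forward selection inside a wrapper: at each step the feature
whose addition maximizes leave-one-out cross-validated accuracy joins the
subset, up to a cap of floor(n_subjects / 10) features (3 at n = 36).
Features are z-scored using training-fold statistics only. Reported
metrics are sensitivity, specificity, accuracy (percent, CR treated as the
positive class by default) and the ROC AUC of the held-out scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve, auc as _auc

__all__ = [
    "Dataset",
    "ClassifierReport",
    "knn_classify",
    "naive_bayes_classify",
    "loo_cv",
    "sequential_forward_select",
    "evaluate",
    "default_feature_cap",
]

#: Variance floor for naive-Bayes class-conditional Gaussians, as a
#: fraction of the overall feature variance.
NB_VAR_FLOOR = 1e-9


@dataclass
class Dataset:
    """Patients x features matrix with binary CR/PR labels."""

    X: pd.DataFrame
    y: np.ndarray                    # labels, e.g. "CR"/"PR"
    positive_class: str = "CR"

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y)
        if len(self.y) != len(self.X):
            raise ValueError("labels and matrix length mismatch")
        if self.X.isna().to_numpy().any():
            raise ValueError("dataset contains missing values")
        classes = set(self.y.tolist())
        if len(classes) != 2:
            raise ValueError("labels must be binary")
        if self.positive_class not in classes:
            raise ValueError("positive_class not among labels")

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def feature_names(self) -> list:
        return list(self.X.columns)


@dataclass
class ClassifierReport:
    """Per-model, per-time-point wrapper result (published-table shape)."""

    model: str
    timepoint: str | None
    n_features: int
    selected: list
    sensitivity: float               # percent
    specificity: float               # percent
    accuracy: float                  # percent
    auc: float
    predictions: pd.DataFrame = dataclass_field(repr=False, default=None)

    def as_dict(self) -> dict:
        return {
            "model": self.model, "timepoint": self.timepoint,
            "n_features": self.n_features, "selected": list(self.selected),
            "sensitivity_pct": self.sensitivity,
            "specificity_pct": self.specificity,
            "accuracy_pct": self.accuracy, "auc": self.auc,
        }


def default_feature_cap(n_subjects: int) -> int:
    """Rule-of-thumb wrapper cap: floor(n_subjects / 10), at least 1."""
    return max(1, n_subjects // 10)


def knn_classify(train_X: np.ndarray, train_y: np.ndarray, test_point,
                 k: int = 3, positive_class: str = "CR"):
    """Majority vote among the k Euclidean-nearest training points.

    Returns (label, score) where score is the fraction of neighbours voting
    for the positive class. A tied vote is resolved to the class of the
    single nearest neighbour (deterministic and local).
    """
    train_X = np.asarray(train_X, dtype=float)
    train_y = np.asarray(train_y)
    x = np.asarray(test_point, dtype=float)
    if k > len(train_y):
        raise ValueError("k exceeds the training-set size")
    d = np.linalg.norm(train_X - x, axis=1)
    order = np.argsort(d, kind="stable")
    nn = order[:k]
    votes_pos = int(np.sum(train_y[nn] == positive_class))
    score = votes_pos / k
    if votes_pos * 2 == k:           # tie: defer to the nearest neighbour
        label = train_y[order[0]]
    else:
        label = positive_class if votes_pos * 2 > k else \
            next(c for c in set(train_y.tolist()) if c != positive_class)
    return label, float(score)


def naive_bayes_classify(train_X: np.ndarray, train_y: np.ndarray, test_point,
                         positive_class: str = "CR"):
    """Gaussian naive Bayes with empirical priors and a variance floor.

    Per-feature Gaussian class-conditionals are fitted per class; the
    posterior is prior x product of likelihoods (features independent).
    Returns (label, posterior of the positive class).
    """
    train_X = np.asarray(train_X, dtype=float)
    train_y = np.asarray(train_y)
    x = np.asarray(test_point, dtype=float)
    classes = sorted(set(train_y.tolist()))
    overall_var = train_X.var(axis=0)
    floor = NB_VAR_FLOOR * np.where(overall_var > 0, overall_var, 1.0)
    log_post = {}
    for c in classes:
        sel = train_y == c
        if sel.sum() < 2:
            raise ValueError("each class needs >= 2 training points")
        mu = train_X[sel].mean(axis=0)
        var = np.maximum(train_X[sel].var(axis=0), floor)
        ll = -0.5 * np.sum(np.log(2.0 * np.pi * var) + (x - mu) ** 2 / var)
        log_post[c] = np.log(sel.mean()) + ll
    shift = max(log_post.values())
    post = {c: np.exp(v - shift) for c, v in log_post.items()}
    z = sum(post.values())
    post = {c: v / z for c, v in post.items()}
    label = max(classes, key=lambda c: (post[c], c == positive_class))
    return label, float(post[positive_class])


def _zscore_fit(X: np.ndarray):
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return mu, sd


def loo_cv(dataset: Dataset, model: str, feature_subset,
           k: int = 3) -> pd.DataFrame:
    """Leave-one-out predictions for one feature subset.

    Standardization (z-scoring) is fitted on each n-1 training fold only
    and applied to the held-out patient. ``model`` is ``"knn"`` or
    ``"nb"``. Returns a frame with true label, prediction and
    positive-class score per patient.
    """
    missing = [f for f in feature_subset if f not in dataset.X.columns]
    if missing:
        raise ValueError(f"unknown features: {missing}")
    if dataset.n < 4:
        raise ValueError("need at least 4 patients for LOO-CV")
    X = dataset.X[list(feature_subset)].to_numpy(dtype=float)
    y = dataset.y
    preds, scores = [], []
    for i in range(dataset.n):
        mask = np.ones(dataset.n, dtype=bool)
        mask[i] = False
        mu, sd = _zscore_fit(X[mask])
        Xtr = (X[mask] - mu) / sd
        xt = (X[i] - mu) / sd
        if model == "knn":
            label, score = knn_classify(Xtr, y[mask], xt, k=k,
                                        positive_class=dataset.positive_class)
        elif model == "nb":
            label, score = naive_bayes_classify(
                Xtr, y[mask], xt, positive_class=dataset.positive_class)
        else:
            raise ValueError(f"unknown model {model!r}")
        preds.append(label)
        scores.append(score)
    return pd.DataFrame({"true": y, "predicted": preds, "score": scores},
                        index=dataset.X.index)


def evaluate(predictions, scores, labels,
             positive_class: str = "CR") -> dict:
    """Sensitivity/specificity/accuracy (percent) and ROC AUC.

    The positive class defaults to CR. AUC comes from a threshold sweep of
    the held-out scores (trapezoid rule); single-class label vectors have
    no ROC and raise.
    """
    y = np.asarray(labels)
    p = np.asarray(predictions)
    s = np.asarray(scores, dtype=float)
    if len({*y.tolist()}) < 2:
        raise ValueError("AUC undefined for single-class labels")
    pos = y == positive_class
    tp = int(np.sum(pos & (p == positive_class)))
    fn = int(np.sum(pos & (p != positive_class)))
    tn = int(np.sum(~pos & (p != positive_class)))
    fp = int(np.sum(~pos & (p == positive_class)))
    fpr, tpr, _ = roc_curve(pos.astype(int), s)
    return {
        "sensitivity_pct": 100.0 * tp / (tp + fn),
        "specificity_pct": 100.0 * tn / (tn + fp),
        "accuracy_pct": 100.0 * (tp + tn) / len(y),
        "auc": float(_auc(fpr, tpr)),
    }


def sequential_forward_select(dataset: Dataset, model: str,
                              max_features: int | None = None,
                              k: int = 3, timepoint: str | None = None):
    """Greedy wrapper feature selection with LOO-CV accuracy.

    At each step every remaining feature is trialled in combination with
    the already-selected ones; the one maximizing LOO accuracy is kept
    (ties broken by earlier feature order, a stable deterministic rule).
    Returns one ClassifierReport per subset size 1..max_features. The cap
    defaults to floor(n/10).
    """
    if max_features is None:
        max_features = default_feature_cap(dataset.n)
    if max_features < 1:
        raise ValueError("max_features must be >= 1")
    max_features = min(max_features, len(dataset.feature_names))

    selected: list = []
    reports = []
    remaining = list(dataset.feature_names)
    for size in range(1, max_features + 1):
        best = None
        for feat in remaining:
            trial = selected + [feat]
            preds = loo_cv(dataset, model, trial, k=k)
            acc = float(np.mean(preds["true"] == preds["predicted"]))
            if best is None or acc > best[0]:
                best = (acc, feat, preds)
        _, feat, preds = best
        selected = selected + [feat]
        remaining.remove(feat)
        metrics = evaluate(preds["predicted"], preds["score"], preds["true"],
                           positive_class=dataset.positive_class)
        reports.append(ClassifierReport(
            model=model, timepoint=timepoint, n_features=size,
            selected=list(selected),
            sensitivity=metrics["sensitivity_pct"],
            specificity=metrics["specificity_pct"],
            accuracy=metrics["accuracy_pct"], auc=metrics["auc"],
            predictions=preds,
        ))
    return reports
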