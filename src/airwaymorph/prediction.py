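"""Group predictability by logistic regression with repeated leave-n-out.

A chosen feature set is evaluated by drawing, in each of ``repeats``
iterations, a uniformly random test subset of ``n_holdout`` subjects (fresh
each repeat, not a partition), fitting a ridge-penalized logistic model on
the remaining subjects, and predicting the held-out ones.  All repeats' test
predictions are pooled before computing metrics, so with the reference
protocol (m = 30, n = 6, 30 repeats) the accuracy resolves to counts out of
180 rather than multiples of 1/6.

Reported metrics (percent): pooled accuracy; TP, the fraction of group-1
test cases predicted group 1 (sensitivity); and FP, the fraction of group-0
test cases predicted group 1 (100 - specificity).  ROC curves and AUC are
computed over the pooled test probabilities and, separately, over the pooled
training predictions.

A small ridge penalty is always applied: with feature sets of order 16 on 24
training subjects the classes are typically linearly separable and the
unpenalized maximum-likelihood estimate diverges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve as _sk_roc_curve

from .volume_io import FeatureTable


@dataclass
class CVConfig:
    """Cross-validation protocol parameters (defaults follow the reference
    protocol: m = 30 subjects, leave 6 out, 30 repeats)."""

    n_holdout: int = 6
    repeats: int = 30
    seed: int = 0
    decision_threshold: float = 0.5
    ridge_penalty: float = 1e-3

    def __post_init__(self) -> None:
        if self.n_holdout < 1:
            raise ValueError("n_holdout must be >= 1")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if not 0.0 < self.decision_threshold < 1.0:
            raise ValueError("decision threshold must be in (0, 1)")
        if self.ridge_penalty < 0:
            raise ValueError("ridge penalty must be non-negative")


@dataclass
class LogisticModel:
    """Fitted logistic model with its training z-score transform."""

    coef: np.ndarray
    intercept: float
    train_mean: np.ndarray
    train_sd: np.ndarray

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        Z = (np.asarray(X, dtype=float) - self.train_mean) / self.train_sd
        eta = Z @ self.coef + self.intercept
        return 1.0 / (1.0 + np.exp(-eta))


@dataclass
class RepeatRecord:
    test_ids: list[str]
    probabilities: np.ndarray
    labels: np.ndarray


@dataclass
class CVResult:
    """Pooled cross-validation metrics plus per-repeat predictions."""

    repeats: list[RepeatRecord]
    accuracy: float  # percent
    tp: float        # percent, sensitivity
    fp: float        # percent, 100 - specificity
    roc_test: tuple[np.ndarray, np.ndarray]
    roc_train: tuple[np.ndarray, np.ndarray]
    auc_test: float
    auc_train: float

    def __post_init__(self) -> None:
        labels = np.concatenate([r.labels for r in self.repeats])
        n1 = int((labels == 1).sum())
        n0 = int((labels == 0).sum())
        # internal identity: accuracy is the label-frequency-weighted
        # combination of sensitivity and specificity over pooled counts
        if n0 and n1:
            expected = (self.tp * n1 + (100.0 - self.fp) * n0) / (n0 + n1)
            assert abs(self.accuracy - expected) < 1e-9, (
                "accuracy/TP/FP internal identity violated"
            )


def fit_logistic(train_features: np.ndarray, train_labels: np.ndarray,
                 ridge_penalty: float = 1e-3) -> LogisticModel:
    """Ridge-penalized logistic regression on z-scored features.

    Features are standardized with the training means/SDs (zero-SD features
    are mapped to constant zero columns, so the penalty drives their
    coefficients to 0).  The penalized binomial log-likelihood is maximized
    with lbfgs; ``ridge_penalty`` is the L2 weight on the standardized
    coefficients (intercept unpenalized).
    """
    X = np.asarray(train_features, dtype=float)
    y = np.asarray(train_labels, dtype=int)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training set contains a single class")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    Z = (X - mean) / sd
    C = 1.0 / ridge_penalty if ridge_penalty > 0 else 1e12
    clf = LogisticRegression(C=C, solver="lbfgs",
                             max_iter=10_000, tol=1e-10)
    clf.fit(Z, y)
    return LogisticModel(coef=clf.coef_.ravel().copy(),
                         intercept=float(clf.intercept_[0]),
                         train_mean=mean, train_sd=sd)


def roc_points(probabilities: np.ndarray, labels: np.ndarray
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """ROC sweep over all distinct thresholds plus trapezoidal AUC.

    Returns ``(fpr, tpr, thresholds, auc)``.  The trapezoidal AUC equals the
    normalized Mann-Whitney U statistic of the probabilities.
    """
    labels = np.asarray(labels, dtype=int)
    if np.unique(labels).size < 2:
        raise ValueError("ROC requires at least one sample per class")
    fpr, tpr, thr = _sk_roc_curve(labels, np.asarray(probabilities, dtype=float))
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, thr, auc


def repeated_leave_n_out(table: FeatureTable, feature_set: list[str],
                         config: CVConfig) -> CVResult:
    """Repeated random-holdout cross-validation of one feature set.

    The feature set is fixed throughout; only the classifier is refitted per
    repeat.  Deterministic given ``config.seed``.
    """
    if not feature_set:
        raise ValueError("feature set is empty")
    missing = [f for f in feature_set if f not in set(table.feature_ids)]
    if missing:
        raise ValueError(f"features missing from table: {missing}")
    m = len(table.data)
    if config.n_holdout >= m:
        raise ValueError(f"n_holdout={config.n_holdout} must be < m={m}")
    X = table.values_for(feature_set)
    y = table.groups.to_numpy(dtype=int)
    ids = np.asarray(table.data.index.astype(str))
    rng = np.random.default_rng(config.seed)

    records: list[RepeatRecord] = []
    train_probs, train_labels = [], []
    for _ in range(config.repeats):
        test_idx = rng.choice(m, size=config.n_holdout, replace=False)
        train_mask = np.ones(m, dtype=bool)
        train_mask[test_idx] = False
        model = fit_logistic(X[train_mask], y[train_mask], config.ridge_penalty)
        records.append(RepeatRecord(
            test_ids=list(ids[test_idx]),
            probabilities=model.predict_proba(X[test_idx]),
            labels=y[test_idx].copy(),
        ))
        train_probs.append(model.predict_proba(X[train_mask]))
        train_labels.append(y[train_mask].copy())

    probs = np.concatenate([r.probabilities for r in records])
    labels = np.concatenate([r.labels for r in records])
    pred = (probs >= config.decision_threshold).astype(int)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    tp = 100.0 * float((pred[labels == 1] == 1).mean()) if n1 else 0.0
    fp = 100.0 * float((pred[labels == 0] == 1).mean()) if n0 else 0.0
    accuracy = 100.0 * float((pred == labels).mean())

    fpr_t, tpr_t, _, auc_t = roc_points(probs, labels)
    tr_probs = np.concatenate(train_probs)
    tr_labels = np.concatenate(train_labels)
    fpr_r, tpr_r, _, auc_r = roc_points(tr_probs, tr_labels)

    return CVResult(repeats=records, accuracy=accuracy, tp=tp, fp=fp,
                    roc_test=(fpr_t, tpr_t), roc_train=(fpr_r, tpr_r),
                    auc_test=auc_t, auc_train=auc_r)
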