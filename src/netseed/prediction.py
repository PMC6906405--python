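"""Disease-prediction models and their evaluation metrics.

Two simple classifiers mirror the usual train-on-discovery /
test-on-replication design: a random-forest on allele dosages (*variant
model*, with mean-decrease-in-impurity feature importances) and a univariate
logistic regression on the polygenic risk score (*PRS model*).  Both are
class-weight balanced so the decision threshold is not degenerate under the
heavy case/control imbalance of a population replication cohort.  Metrics:
confusion matrix, sensitivity, specificity, accuracy, balanced accuracy
(mean of sensitivity and specificity), and the Mann–Whitney AUC with a
DeLong 95% confidence interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts of a binary decision against truth (cases are positive)."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionMatrix":
        t = np.asarray(y_true).astype(bool)
        p = np.asarray(y_pred).astype(bool)
        return cls(
            tp=int(np.sum(t & p)), fn=int(np.sum(t & ~p)),
            fp=int(np.sum(~t & p)), tn=int(np.sum(~t & ~p)),
        )


@dataclass
class EvalReport:
    """Threshold metrics, ranking metrics and feature importances."""

    accuracy: float
    specificity: float
    sensitivity: float
    balanced_accuracy: float
    auc: float = float("nan")
    auc_ci: tuple[float, float] = (float("nan"), float("nan"))
    importances: dict[str, float] = field(default_factory=dict)
    confusion: ConfusionMatrix | None = None


def confusion_metrics(cm: ConfusionMatrix) -> EvalReport:
    """Sensitivity, specificity, accuracy and balanced accuracy from counts."""
    pos, neg = cm.tp + cm.fn, cm.fp + cm.tn
    if pos == 0 or neg == 0:
        raise ValueError("both classes must be present to compute metrics")
    sens = cm.tp / pos
    spec = cm.tn / neg
    acc = (cm.tp + cm.tn) / (pos + neg)
    return EvalReport(
        accuracy=acc,
        specificity=spec,
        sensitivity=sens,
        balanced_accuracy=(sens + spec) / 2,
        confusion=cm,
    )


def auc_with_ci(scores, labels, alpha: float = 0.05) -> tuple[float, float, float]:
    """Mann–Whitney AUC with a DeLong confidence interval.

    AUC is the probability a random case outscores a random control, ties
    counted one half.  The variance uses DeLong's structural-component
    estimator; the normal-approximation CI is clipped to [0, 1].
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos, neg = scores[labels], scores[~labels]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    # midranks over the pooled sample give the placement values
    combined = np.concatenate([pos, neg])
    order = np.argsort(combined, kind="mergesort")
    ranks = np.empty(m + n)
    sorted_vals = combined[order]
    i = 0
    while i < m + n:
        j = i
        while j + 1 < m + n and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i: j + 1]] = (i + j) / 2 + 1
        i = j + 1
    r_pos = ranks[:m]
    auc = (r_pos.sum() - m * (m + 1) / 2) / (m * n)
    # DeLong structural components
    v10 = np.array([(np.sum(x > neg) + 0.5 * np.sum(x == neg)) / n for x in pos])
    v01 = np.array([(np.sum(pos > y) + 0.5 * np.sum(pos == y)) / m for y in neg])
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + \
          (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    z = norm.isf(alpha / 2)
    half = z * np.sqrt(var)
    return float(auc), float(max(0.0, auc - half)), float(min(1.0, auc + half))


def fit_variant_model(
    dosages,
    labels,
    feature_names=None,
    rng: int | np.random.Generator | None = 0,
    n_estimators: int = 500,
    max_depth: int | None = None,
):
    """Class-balanced random forest on allele dosages.

    Returns the fitted classifier and the normalised mean-decrease-in-impurity
    importances (they sum to 1 whenever any split occurred).  Missing dosages
    are mean-imputed before fitting.
    """
    X = np.asarray(dosages, dtype=float)
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels must include both classes")
    col_mean = np.nanmean(X, axis=0)
    nr, nc = np.where(np.isnan(X))
    X[nr, nc] = col_mean[nc]
    seed = rng if isinstance(rng, (int, np.integer)) or rng is None else \
        int(rng.integers(2**31))
    clf = RandomForestClassifier(
        n_estimators=n_estimators,
        max_depth=max_depth,
        class_weight="balanced",
        random_state=seed,
    )
    clf.fit(X, y)
    names = list(feature_names) if feature_names is not None else \
        [f"feature{j + 1}" for j in range(X.shape[1])]
    imp = clf.feature_importances_
    total = imp.sum()
    importances = {nm: float(v / total) if total > 0 else 0.0 for nm, v in zip(names, imp)}
    return clf, importances


def fit_prs_model(train_scores, train_labels, threshold: float = 0.5):
    """Class-balanced univariate logistic classifier on the PRS.

    Predicted class is 1 when the class-weighted case probability exceeds
    ``threshold``.  Constant training scores leave the coefficient
    unidentifiable and raise.
    """
    s = np.asarray(train_scores, dtype=float).reshape(-1, 1)
    y = np.asarray(train_labels).astype(int)
    if np.ptp(s) == 0:
        raise ValueError("constant PRS: classifier undefined")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels must include both classes")
    clf = LogisticRegression(class_weight="balanced", solver="lbfgs", max_iter=1000)
    clf.fit(s, y)
    clf.decision_threshold_ = threshold
    return clf


def evaluate_classifier(clf, X_test, y_test, threshold: float | None = None) -> EvalReport:
    """Score a fitted classifier on a held-out panel."""
    X = np.asarray(X_test, dtype=float)
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    col_mean = np.nanmean(X, axis=0)
    nr, nc = np.where(np.isnan(X))
    X[nr, nc] = col_mean[nc]
    y = np.asarray(y_test).astype(int)
    prob = clf.predict_proba(X)[:, 1]
    thr = threshold if threshold is not None else getattr(clf, "decision_threshold_", 0.5)
    pred = (prob > thr).astype(int)
    report = confusion_metrics(ConfusionMatrix.from_predictions(y, pred))
    report.auc, lo, hi = auc_with_ci(prob, y)
    report.auc_ci = (lo, hi)
    if hasattr(clf, "feature_importances_"):
        imp = clf.feature_importances_
        total = imp.sum()
        report.importances = {
            f"feature{j + 1}": float(v / total) if total > 0 else 0.0
            for j, v in enumerate(imp)
        }
    return report
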