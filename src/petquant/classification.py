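"""Feature selection, LOOCV linear-SVM classification, and paired
classifier comparison via Cochran's Q.

The two feature families (regional DVR means vs. whole-brain Haralick
texture) are evaluated with the same protocol: cap the number of features
by a samples-per-feature ratio, drop one member of every feature pair with
|Pearson r| above a threshold, rank the survivors by the magnitude of their
standardized logistic-regression coefficients, keep the top k, and estimate
generalization by leave-one-out cross-validation of a linear soft-margin
SVM (features z-scored inside each training fold -- never with the held-out
subject).  The two per-subject binary response vectors are then compared
with Cochran's Q, which for two classifiers reduces to the uncorrected
McNemar statistic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

__all__ = [
    "FeatureTable",
    "SelectionResult",
    "LOOCVResult",
    "PerformanceMetrics",
    "CochranQResult",
    "ClassifierComparison",
    "max_features",
    "correlation_filter",
    "rank_by_logistic",
    "select_features",
    "loocv_svm",
    "performance_metrics",
    "cochran_q",
    "compare_classifiers",
]

logger = logging.getLogger(__name__)

POSITIVE_LABEL = "AD"
NEGATIVE_LABEL = "HC"


@dataclass
class FeatureTable:
    """Subjects x named numeric features, with binary group labels."""

    subject_ids: list
    labels: list                    # "AD" / "HC" per subject
    features: pd.DataFrame          # numeric, columns = feature names

    def __post_init__(self) -> None:
        if len(self.subject_ids) != len(self.labels) or \
                len(self.subject_ids) != len(self.features):
            raise ValueError("subjects, labels and feature rows must align")
        if self.features.columns.duplicated().any():
            raise ValueError("feature names must be unique")
        if not np.all(np.isfinite(self.features.to_numpy(dtype=float))):
            raise ValueError("features must be finite")
        bad = set(self.labels) - {POSITIVE_LABEL, NEGATIVE_LABEL}
        if bad:
            raise ValueError(f"unknown labels: {sorted(bad)}")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, id_col: str = "subject_id",
                       group_col: str = "group") -> "FeatureTable":
        feats = df.drop(columns=[id_col, group_col])
        return cls(list(df[id_col]), list(df[group_col]), feats.reset_index(drop=True))

    def to_dataframe(self) -> pd.DataFrame:
        out = self.features.copy()
        out.insert(0, "group", self.labels)
        out.insert(0, "subject_id", self.subject_ids)
        return out

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def y(self) -> np.ndarray:
        """Binary target: 1 for the positive (patient) class."""
        return np.array([1 if lbl == POSITIVE_LABEL else 0 for lbl in self.labels])


@dataclass
class SelectionResult:
    retained_after_correlation: list
    ranking: list                   # (name, importance), descending
    selected: list                  # exactly k names

    def __post_init__(self) -> None:
        ranked_names = [n for n, _ in self.ranking]
        if not set(self.selected) <= set(self.retained_after_correlation):
            raise ValueError("selected features must survive the correlation filter")
        if not set(self.selected) <= set(ranked_names):
            raise ValueError("selected features must appear in the ranking")


@dataclass
class LOOCVResult:
    subject_ids: list
    true_labels: list
    predicted_labels: list

    def __post_init__(self) -> None:
        if not (len(self.subject_ids) == len(self.true_labels)
                == len(self.predicted_labels)):
            raise ValueError("per-subject vectors must align")

    @property
    def n_folds(self) -> int:
        return len(self.subject_ids)


@dataclass
class PerformanceMetrics:
    accuracy: float
    sensitivity: float
    specificity: float
    balanced_accuracy: float

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "balanced_accuracy": self.balanced_accuracy,
        }


@dataclass
class CochranQResult:
    q: float
    df: int
    p_value: float
    reject_at_alpha: bool
    alpha: float = 0.05


@dataclass
class ClassifierComparison:
    kinetic_selection: SelectionResult
    texture_selection: SelectionResult
    kinetic_result: LOOCVResult
    texture_result: LOOCVResult
    kinetic_metrics: PerformanceMetrics
    texture_metrics: PerformanceMetrics
    cochran: CochranQResult
    response: str = "predicted_positive"


# ---------------------------------------------------------------------------
# feature selection
# ---------------------------------------------------------------------------

def max_features(n_per_class: tuple[int, int], ratio: float = 10.0,
                 per_class: bool = False) -> int:
    """Feature cap from a samples-per-feature ratio.

    Default reading: ``floor(total_n / ratio)`` (a (19, 21) cohort at ratio
    10 allows 4 features).  ``per_class=True`` uses the stricter
    ``floor(min_class / ratio)``.
    """
    if min(n_per_class) < 1:
        raise ValueError("class counts must be at least 1")
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    k = int(min(n_per_class) // ratio) if per_class else int(sum(n_per_class) // ratio)
    if k < 1:
        raise ValueError("cohort too small for even one feature at this ratio")
    return k


def correlation_filter(table: FeatureTable, threshold: float = 0.9) -> list:
    """Drop one member of every feature pair correlated above ``threshold``.

    Zero-variance features are removed first (and logged).  Then, while any
    pair has |Pearson r| strictly above the threshold, the member of the
    worst pair with the larger mean absolute correlation to all other
    remaining features is removed; ties break toward removing the
    alphabetically later name.  Returns the retained names in original
    column order.
    """
    if table.n_subjects < 2:
        raise ValueError("at least two subjects are required")
    feats = table.features
    keep = []
    for name in feats.columns:
        if feats[name].std(ddof=0) == 0:
            logger.warning("dropping zero-variance feature %r", name)
        else:
            keep.append(name)
    current = list(keep)
    while len(current) > 1:
        corr = feats[current].corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        worst = np.nanmax(corr)
        if not (worst > threshold):
            break
        i, j = np.unravel_index(np.nanargmax(corr), corr.shape)
        mean_i = np.nanmean(np.delete(corr[i], [i]))
        mean_j = np.nanmean(np.delete(corr[j], [j]))
        if mean_i > mean_j:
            drop = current[i]
        elif mean_j > mean_i:
            drop = current[j]
        else:
            drop = max(current[i], current[j])   # alphabetically later
        current.remove(drop)
    return [n for n in feats.columns if n in current]


def rank_by_logistic(table: FeatureTable, feature_names=None,
                     c: float = 1.0) -> list:
    """Rank features by |standardized logistic-regression coefficient|.

    One L2-regularized logistic model is fitted on z-scored features (light
    regularization keeps the fit defined even under complete separation);
    importance is the absolute coefficient, descending, ties broken
    alphabetically.  Returns a list of ``(name, importance)``.
    """
    names = list(feature_names) if feature_names is not None \
        else list(table.features.columns)
    y = table.y
    if len(set(y)) < 2:
        raise ValueError("both classes must be present")
    x = table.features[names].to_numpy(dtype=float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    if np.any(sd == 0):
        raise ValueError("zero-variance feature passed to ranking")
    xs = (x - mu) / sd
    model = LogisticRegression(penalty="l2", C=c, solver="lbfgs", max_iter=5000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(xs, y)
    if model.n_iter_[0] >= 5000:
        logger.warning("logistic ranking hit the iteration cap; "
                       "L2 regularization (C=%.3g) kept the fit defined", c)
    importance = np.abs(model.coef_[0])
    order = sorted(range(len(names)), key=lambda i: (-importance[i], names[i]))
    return [(names[i], float(importance[i])) for i in order]


def select_features(table: FeatureTable, k: int | None = None,
                    corr_threshold: float = 0.9, ratio: float = 10.0,
                    per_class: bool = False) -> SelectionResult:
    """Full selection stage: ratio cap -> correlation filter -> logistic rank."""
    if k is None:
        n_pos = int(table.y.sum())
        k = max_features((n_pos, table.n_subjects - n_pos), ratio, per_class)
    retained = correlation_filter(table, corr_threshold)
    ranking = rank_by_logistic(table, retained)
    selected = [name for name, _ in ranking[:k]]
    return SelectionResult(retained, ranking, selected)


# ---------------------------------------------------------------------------
# LOOCV linear SVM
# ---------------------------------------------------------------------------

def loocv_svm(table: FeatureTable, selected, cost: float = 1.0) -> LOOCVResult:
    """Leave-one-out cross-validation of a linear soft-margin SVM.

    Each subject in turn is the single-item test set; the remaining n-1
    subjects are z-scored (their own statistics only) and used to train an
    SVM with fixed cost; the held-out subject is standardized with the
    training statistics and classified.  No information from the held-out
    subject enters training.
    """
    selected = list(selected)
    if not selected:
        raise ValueError("no features selected")
    x = table.features[selected].to_numpy(dtype=float)
    y = table.y
    n = table.n_subjects
    if min(int(y.sum()), n - int(y.sum())) < 2:
        raise ValueError("at least two subjects per class are required")
    preds = []
    for i in range(n):
        train = np.ones(n, dtype=bool)
        train[i] = False
        if len(set(y[train])) < 2:
            raise ValueError("a training fold lost a class entirely")
        mu = x[train].mean(axis=0)
        sd = x[train].std(axis=0, ddof=0)
        sd = np.where(sd > 0, sd, 1.0)
        clf = SVC(kernel="linear", C=cost)
        clf.fit((x[train] - mu) / sd, y[train])
        pred = int(clf.predict(((x[i] - mu) / sd)[None, :])[0])
        preds.append(POSITIVE_LABEL if pred == 1 else NEGATIVE_LABEL)
    return LOOCVResult(list(table.subject_ids), list(table.labels), preds)


def performance_metrics(result: LOOCVResult,
                        positive: str = POSITIVE_LABEL) -> PerformanceMetrics:
    """Accuracy, sensitivity, specificity and balanced accuracy."""
    truth = np.array(result.true_labels)
    pred = np.array(result.predicted_labels)
    pos = truth == positive
    if pos.sum() == 0 or (~pos).sum() == 0:
        raise ValueError("both classes must appear among the true labels")
    accuracy = float((truth == pred).mean())
    sensitivity = float((pred[pos] == positive).mean())
    specificity = float((pred[~pos] != positive).mean())
    balanced = 0.5 * (sensitivity + specificity)
    return PerformanceMetrics(accuracy, sensitivity, specificity, balanced)


# ---------------------------------------------------------------------------
# Cochran's Q
# ---------------------------------------------------------------------------

def cochran_q(responses: np.ndarray, alpha: float = 0.05) -> CochranQResult:
    """Cochran's Q test for equal proportions of a binary response across
    k matched classifiers.

    ``responses`` is subjects x classifiers with entries in {0, 1}.
    ``Q = k(k-1) sum_j (G_j - Gbar)^2 / (k sum_i L_i - sum_i L_i^2)`` with
    column totals G_j and row totals L_i; df = k - 1; p from the chi-square
    upper tail.  Rows with all-equal responses contribute nothing; when the
    denominator is zero Q is defined as 0 (p = 1).  For k = 2 this equals
    the uncorrected McNemar statistic ``(b - c)^2 / (b + c)``.
    """
    r = np.asarray(responses)
    if r.ndim != 2 or r.shape[1] < 2:
        raise ValueError("responses must be 2-D with at least two classifiers")
    if r.shape[0] < 2:
        raise ValueError("at least two subjects are required")
    if not np.isin(r, (0, 1)).all():
        raise ValueError("responses must be binary (0/1)")
    r = r.astype(float)
    k = r.shape[1]
    g = r.sum(axis=0)
    l = r.sum(axis=1)
    denom = k * l.sum() - (l ** 2).sum()
    if denom == 0:
        q = 0.0
    else:
        q = float(k * (k - 1) * ((g - g.mean()) ** 2).sum() / denom)
    df = k - 1
    p = float(chi2.sf(q, df)) if q > 0 else 1.0
    return CochranQResult(q, df, p, reject_at_alpha=p < alpha, alpha=alpha)


def compare_classifiers(kinetic_table: FeatureTable,
                        texture_table: FeatureTable,
                        corr_threshold: float = 0.9, ratio: float = 10.0,
                        cost: float = 1.0, alpha: float = 0.05,
                        response: str = "predicted_positive"
                        ) -> ClassifierComparison:
    """Run selection + LOOCV SVM per feature family and compare the two
    classifiers with Cochran's Q.

    ``response`` chooses the binary response entering Q:
    ``"predicted_positive"`` (default; the null hypothesis is equal
    proportions of patient calls) or ``"correct"``.
    """
    if list(kinetic_table.subject_ids) != list(texture_table.subject_ids):
        raise ValueError("both tables must list the same subjects in order")
    if list(kinetic_table.labels) != list(texture_table.labels):
        raise ValueError("labels disagree between the two tables")
    if response not in ("predicted_positive", "correct"):
        raise ValueError("response must be 'predicted_positive' or 'correct'")

    results = {}
    selections = {}
    metrics = {}
    for key, tab in (("kinetic", kinetic_table), ("texture", texture_table)):
        sel = select_features(tab, corr_threshold=corr_threshold, ratio=ratio)
        res = loocv_svm(tab, sel.selected, cost=cost)
        selections[key] = sel
        results[key] = res
        metrics[key] = performance_metrics(res)

    def binary(res: LOOCVResult) -> np.ndarray:
        pred = np.array(res.predicted_labels)
        if response == "predicted_positive":
            return (pred == POSITIVE_LABEL).astype(int)
        return (pred == np.array(res.true_labels)).astype(int)

    q_res = cochran_q(
        np.column_stack([binary(results["kinetic"]), binary(results["texture"])]),
        alpha=alpha)
    return ClassifierComparison(
        selections["kinetic"], selections["texture"],
        results["kinetic"], results["texture"],
        metrics["kinetic"], metrics["texture"], q_res, response=response)
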