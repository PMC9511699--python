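"""Group statistics and leave-one-out diagnostic-model evaluation.

Mirrors the workflow the independence test is meant to audit: per-feature
group comparisons (pairwise t-tests, one-way ANOVA), leave-one-out
cross-validated logistic regression for two-class problems, a random
forest for multicategory problems, and ROC/AUC with a Youden-optimal
operating point.

Instances are per-ROI feature rows by default — deliberately reproducing
the common (and leakage-prone) practice of treating every frame's ROI as a
separate training instance; aggregation to case level is available via
``aggregate_by_case``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .core_io import FEATURE_COLUMNS
from .errors import DegenerateFoldError, SampleSizeError

__all__ = [
    "ClassificationReport",
    "group_feature_stats",
    "make_model",
    "loo_cv_scores",
    "roc_auc",
    "multicategory_eval",
    "aggregate_by_case",
]


@dataclass
class ClassificationReport:
    """ROC summary for one binary (or one-vs-rest) task.

    ``sensitivity``/``specificity`` are percentages at the Youden-optimal
    threshold (max of TPR - FPR over the ROC curve).
    """

    task: str
    auc: float
    sensitivity: float
    specificity: float
    threshold: float
    n: int
    scores: np.ndarray = field(repr=False)
    labels: np.ndarray = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "auc": self.auc,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "threshold": self.threshold,
            "n": self.n,
        }


def group_feature_stats(
    features: pd.DataFrame,
    feature_cols: list[str] | None = None,
    group_col: str = "group",
) -> pd.DataFrame:
    """Per-feature group means +- standard errors, pairwise two-sided
    unpaired t-tests, and one-way ANOVA across all groups.

    One row per feature; mean/SE columns are named ``mean_<group>`` /
    ``se_<group>``, pairwise p-values ``p_<a>_vs_<b>``, and the ANOVA
    p-value ``p_anova``.
    """
    feature_cols = feature_cols or FEATURE_COLUMNS
    groups = sorted(features[group_col].unique())
    if len(groups) < 2:
        raise SampleSizeError("group statistics need >= 2 groups")
    by_group = {g: features[features[group_col] == g] for g in groups}
    for g, sub in by_group.items():
        if len(sub) < 2:
            raise SampleSizeError(f"group {g!r} has fewer than 2 samples")

    rows = []
    for feat in feature_cols:
        row: dict = {"feature": feat}
        samples = {g: by_group[g][feat].to_numpy(dtype=float) for g in groups}
        for g in groups:
            row[f"mean_{g}"] = samples[g].mean()
            row[f"se_{g}"] = stats.sem(samples[g])
        for a, b in combinations(groups, 2):
            row[f"p_{a}_vs_{b}"] = float(
                stats.ttest_ind(samples[a], samples[b]).pvalue
            )
        row["p_anova"] = float(stats.f_oneway(*samples.values()).pvalue)
        rows.append(row)
    return pd.DataFrame(rows)


def make_model(model: str, seed: int | None = None) -> BaseEstimator:
    """Build a classifier pipeline by name.

    ``logistic``: standardized features + essentially unregularized logistic
    regression (a tiny ridge keeps the solver stable).  ``random_forest``:
    100 trees, sqrt(p) features per split, seeded.
    """
    if model == "logistic":
        return make_pipeline(
            StandardScaler(),
            LogisticRegression(C=1e4, max_iter=5000),
        )
    if model == "random_forest":
        return RandomForestClassifier(
            n_estimators=100, max_features="sqrt", random_state=seed
        )
    raise ValueError(f"unknown model {model!r}")


def loo_cv_scores(
    features: np.ndarray | pd.DataFrame,
    labels: np.ndarray | pd.Series,
    model: str | BaseEstimator = "logistic",
    seed: int | None = None,
) -> np.ndarray:
    """Leave-one-out (round-robin) out-of-fold class-probability scores.

    Each sample is scored by a fresh model trained on all other samples;
    any preprocessing (scaling) is fit inside each training fold so no test
    information leaks in.  Returns an ``(n, K)`` matrix of class
    probabilities with classes in sorted label order.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    n = X.shape[0]
    if n < 3:
        raise SampleSizeError("leave-one-out needs at least 3 samples")
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < 2:
        lonely = classes[counts.argmin()]
        raise DegenerateFoldError(
            f"class {lonely!r} has a single sample; leaving it out produces "
            "a single-class training fold"
        )
    estimator = make_model(model, seed) if isinstance(model, str) else model

    scores = np.empty((n, classes.size))
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        est = clone(estimator)
        est.fit(X[mask], y[mask])
        proba = est.predict_proba(X[i : i + 1])[0]
        # training folds always contain every class (counts >= 2)
        order = np.searchsorted(classes, est.classes_)
        scores[i, order] = proba
        mask[i] = True
    return scores


def roc_auc(
    scores: np.ndarray,
    labels: np.ndarray,
    positive_label=1,
    task: str | None = None,
) -> ClassificationReport:
    """ROC analysis of per-sample scores against binary labels.

    AUC follows the Mann-Whitney pair-counting definition (probability that
    a random positive outscores a random negative, ties counting 1/2),
    computed via midranks.  The operating point maximizes Youden's J.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels) == positive_label
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise SampleSizeError("roc_auc needs both classes present")
    ranks = stats.rankdata(scores)  # midranks give ties weight 1/2
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    fpr, tpr, thresholds = roc_curve(y.astype(int), scores)
    best = int(np.argmax(tpr - fpr))
    return ClassificationReport(
        task=task or f"vs_{positive_label}",
        auc=float(auc),
        sensitivity=float(tpr[best] * 100.0),
        specificity=float((1.0 - fpr[best]) * 100.0),
        threshold=float(thresholds[best]),
        n=int(y.size),
        scores=scores,
        labels=np.asarray(labels),
    )


def multicategory_eval(
    features: np.ndarray | pd.DataFrame,
    labels: np.ndarray | pd.Series,
    seed: int | None = 0,
) -> list[ClassificationReport]:
    """One-vs-rest ROC/AUC per class from random-forest LOO scores."""
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size < 3:
        raise SampleSizeError("multicategory evaluation needs >= 3 classes")
    scores = loo_cv_scores(features, y, model="random_forest", seed=seed)
    return [
        roc_auc(
            scores[:, k],
            (y == cls).astype(int),
            positive_label=1,
            task=f"{cls}_vs_rest",
        )
        for k, cls in enumerate(classes)
    ]


def aggregate_by_case(features: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-ROI rows to one mean feature row per case.

    The case-level alternative to per-ROI instances: removes the within-case
    dependence that inflates frame-level cross-validation.
    """
    keep = ["case_id", "group"] + FEATURE_COLUMNS
    return (
        features[keep]
        .groupby(["case_id", "group"], as_index=False)
        .mean()
    )
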