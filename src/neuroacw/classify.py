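"""Classification and feature-scoring layer.

Three analyses quantify how informative each timescale is:

* **variability split AUROC** — subjects are labelled high/low
  variability by the median of their region-averaged resting ACW; a
  logistic model then predicts the label from task-state values and is
  scored by AUROC.
* **core-periphery classification** — regions (class ``core`` = 1 vs
  ``periphery`` = 0) are classified from their ACW features with
  logistic regression or an RBF-kernel SVM under stratified 20-fold
  cross-validation; features are standardized inside each training fold
  only. Metrics are reported as percentages (accuracy, precision,
  recall with ``core`` the positive class) plus AUROC x 100.
* **mutual information** — a nearest-neighbour estimate (k = 3, nats) of
  the dependence between one feature and the binary label; zero for
  independent pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.feature_selection import mutual_info_classif
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    accuracy_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "ClassifierReport",
    "variability_split_auroc",
    "cp_classification",
    "mutual_information_score",
]

CLASSIFIERS = ("logistic", "svm_rbf")
FEATURE_SETS = ("both", "acw50", "acw0")


@dataclass(frozen=True)
class ClassifierReport:
    """Cross-validated metrics for one classifier / feature-set pair.

    ``accuracy``, ``precision``, ``recall`` and ``auroc`` are fold
    means on the 0-100 scale; per-fold values are kept for inspection.
    """

    classifier: str
    feature_set: str
    n_folds: int
    accuracy: float
    precision: float
    recall: float
    auroc: float
    fold_metrics: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "classifier": self.classifier,
            "feature_set": self.feature_set,
            "n_folds": self.n_folds,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "auroc": self.auroc,
        }


def variability_split_auroc(
    rest_by_subject: pd.Series, task_by_subject: pd.Series
) -> float:
    """AUROC for recovering the rest-based variability split from task values.

    Subjects above the rest median are the 'high variability' class.
    A logistic model (one feature: the subject's region-averaged task
    ACW) provides the scores; because the model is monotone in its
    single feature, the AUROC is rank-based in the task values.
    """
    if not rest_by_subject.index.equals(task_by_subject.index):
        raise ValueError("rest and task series must be indexed by the same subjects")
    if len(rest_by_subject) < 6:
        raise ValueError("need at least 6 subjects")
    labels = (rest_by_subject > rest_by_subject.median()).to_numpy().astype(int)
    if labels.min() == labels.max():
        raise ValueError("variability split produced a single class")
    features = task_by_subject.to_numpy().reshape(-1, 1)
    model = make_pipeline(StandardScaler(), LogisticRegression())
    model.fit(features, labels)
    scores = model.predict_proba(features)[:, 1]
    return float(roc_auc_score(labels, scores))


def _make_classifier(name: str):
    if name == "logistic":
        return LogisticRegression(max_iter=1000)
    if name == "svm_rbf":
        return SVC(kernel="rbf")
    raise ValueError(f"classifier must be one of {CLASSIFIERS}")


def cp_classification(
    features: pd.DataFrame,
    labels,
    *,
    classifier: str = "logistic",
    feature_set: str = "both",
    n_folds: int = 20,
    seed: int = 0,
) -> ClassifierReport:
    """Stratified k-fold core/periphery classification from ACW features.

    ``features`` must contain ``acw50_ms`` and ``acw0_ms`` columns (one
    row per sample); ``labels`` are ``core`` / ``periphery`` strings.
    Standardization is fit on each training fold only.
    """
    columns = {
        "both": ["acw50_ms", "acw0_ms"],
        "acw50": ["acw50_ms"],
        "acw0": ["acw0_ms"],
    }
    if feature_set not in columns:
        raise ValueError(f"feature_set must be one of {FEATURE_SETS}")
    X = features[columns[feature_set]].to_numpy(float)
    y = (np.asarray(labels) == "core").astype(int)
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    if len(y) < n_folds:
        raise ValueError(f"need at least n_folds={n_folds} samples")
    splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    rows = []
    for fold, (train, test) in enumerate(splitter.split(X, y)):
        model = make_pipeline(StandardScaler(), _make_classifier(classifier))
        model.fit(X[train], y[train])
        pred = model.predict(X[test])
        score = model.decision_function(X[test])
        rows.append(
            {
                "fold": fold,
                "accuracy": accuracy_score(y[test], pred) * 100,
                "precision": precision_score(y[test], pred, zero_division=0) * 100,
                "recall": recall_score(y[test], pred, zero_division=0) * 100,
                "auroc": (
                    roc_auc_score(y[test], score) * 100
                    if len(np.unique(y[test])) == 2
                    else np.nan
                ),
            }
        )
    folds = pd.DataFrame(rows)
    means = folds.drop(columns="fold").mean()
    return ClassifierReport(
        classifier=classifier,
        feature_set=feature_set,
        n_folds=n_folds,
        accuracy=float(means["accuracy"]),
        precision=float(means["precision"]),
        recall=float(means["recall"]),
        auroc=float(means["auroc"]),
        fold_metrics=folds,
    )


def mutual_information_score(
    feature_values, labels, *, n_neighbors: int = 3, seed: int = 0
) -> float:
    """k-NN mutual information (nats) between a feature and binary labels."""
    feature_values = np.asarray(feature_values, float).reshape(-1, 1)
    y = np.asarray(labels)
    if feature_values.shape[0] < 50:
        raise ValueError("need at least 50 samples for a stable MI estimate")
    if np.unique(y).size < 2:
        raise ValueError("labels are degenerate (single class)")
    score = mutual_info_classif(
        feature_values, y, n_neighbors=n_neighbors, random_state=seed
    )
    return float(max(score[0], 0.0))
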