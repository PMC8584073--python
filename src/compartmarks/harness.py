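"""Seven-classifier benchmark under 10-fold stratified cross-validation.

The battery: Gaussian Naive Bayes (GNB), K-Nearest Neighbors with k=5 (KNN),
Linear Discriminant Analysis (LDA), AdaBoost (ADB), RBF-kernel SVM with
Platt-calibrated probabilities (SVM), a one-hidden-layer (100 ReLU units)
multi-layer perceptron (MLP), and a 150-tree random forest (RFO); remaining
hyperparameters are scikit-learn defaults.

All classifiers share one stratified fold assignment so rows are comparable.
Metrics per classifier: support-weighted recall / precision / F-score pooled
across folds, pooled accuracy, mean and sample-SD of per-fold AUCs from the
predicted class-A probability, and RMSE of that probability against the 0/1
label.  Support-weighted recall is algebraically identical to accuracy; both
are reported, mirroring the usual benchmark-table layout.

Features are standardized (train-fold mean/variance) for the distance- and
margin-based models (GNB, KNN, LDA, SVM, MLP); the tree ensembles see raw
values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FeatureMatrix

METRIC_COLUMNS = ["R", "P", "F-Score", "ACC", "AUC", "SD", "RMSE"]


@dataclass(frozen=True)
class ClassifierSpec:
    """A named battery entry; ``build(seed)`` returns a fresh estimator."""

    name: str
    build: Callable[[int], object]
    standardize: bool = True


def default_battery() -> list[ClassifierSpec]:
    return [
        ClassifierSpec("GNB", lambda seed: GaussianNB()),
        ClassifierSpec("KNN", lambda seed: KNeighborsClassifier(n_neighbors=5)),
        ClassifierSpec("LDA", lambda seed: LinearDiscriminantAnalysis()),
        ClassifierSpec(
            "ADB",
            lambda seed: AdaBoostClassifier(random_state=seed),
            standardize=False,
        ),
        ClassifierSpec(
            # RBF-kernel SVM; Platt-style sigmoid calibration supplies the
            # class probabilities AUC and RMSE need
            "SVM",
            lambda seed: CalibratedClassifierCV(
                SVC(kernel="rbf", random_state=seed),
                method="sigmoid",
                ensemble=False,
            ),
        ),
        ClassifierSpec(
            "MLP",
            lambda seed: MLPClassifier(
                hidden_layer_sizes=(100,), activation="relu", random_state=seed
            ),
        ),
        ClassifierSpec(
            "RFO",
            lambda seed: RandomForestClassifier(n_estimators=150, random_state=seed),
            standardize=False,
        ),
    ]


def stratified_kfold(
    labels: Sequence, k: int = 10, seed: int = 0
) -> list[np.ndarray]:
    """k disjoint test index sets preserving class proportions within one
    sample per fold; deterministic given the seed."""
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"every class needs >= k={k} members, got "
            f"{dict(zip(classes.tolist(), counts.tolist()))}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros(len(y)), y)]


@dataclass
class MetricsRow:
    recall_w: float
    precision_w: float
    f1_w: float
    accuracy: float
    auc_mean: float
    auc_sd: float
    rmse: float

    def as_dict(self) -> dict[str, float]:
        return {
            "R": self.recall_w,
            "P": self.precision_w,
            "F-Score": self.f1_w,
            "ACC": self.accuracy,
            "AUC": self.auc_mean,
            "SD": self.auc_sd,
            "RMSE": self.rmse,
        }


def compute_metrics(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    prob_a: np.ndarray,
    folds: Sequence[np.ndarray],
) -> MetricsRow:
    """Pooled classification metrics plus per-fold AUC mean/SD.

    ``y_true``/``y_pred`` are "A"/"B" label vectors over all samples;
    ``prob_a`` the predicted probability of class A; ``folds`` the test index
    sets.  A fold whose test set contains a single class has no defined AUC
    and raises (choose a different seed or smaller k).
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    prob_a = np.asarray(prob_a, dtype=np.float64)
    if not (len(y_true) == len(y_pred) == len(prob_a)):
        raise ValueError("metric input length mismatch")
    if np.any((prob_a < 0) | (prob_a > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    y01 = (y_true == "A").astype(np.int64)
    aucs = []
    for i, test in enumerate(folds):
        if len(np.unique(y01[test])) < 2:
            raise ValueError(
                f"fold {i} has a single class in its test set; AUC undefined "
                "— use a different seed or smaller k"
            )
        aucs.append(roc_auc_score(y01[test], prob_a[test]))
    aucs = np.asarray(aucs)
    return MetricsRow(
        recall_w=float(recall_score(y_true, y_pred, average="weighted")),
        precision_w=float(
            precision_score(y_true, y_pred, average="weighted", zero_division=0)
        ),
        f1_w=float(f1_score(y_true, y_pred, average="weighted")),
        accuracy=float(accuracy_score(y_true, y_pred)),
        auc_mean=float(aucs.mean()),
        auc_sd=float(aucs.std(ddof=1)) if len(aucs) > 1 else 0.0,
        rmse=float(np.sqrt(np.mean((prob_a - y01) ** 2))),
    )


@dataclass
class ClassifierReport:
    """Per-classifier metrics plus the arithmetic-mean row and fold bookkeeping."""

    table: pd.DataFrame  # index: classifier names + "Mean"; columns METRIC_COLUMNS
    folds: list[np.ndarray] = field(repr=False, default_factory=list)
    seed: int = 0
    k: int = 10

    @property
    def mean_row(self) -> pd.Series:
        return self.table.loc["Mean"]

    def to_tsv(self, path) -> None:
        self.table.round(4).to_csv(path, sep="\t", index_label="Classifier")


def evaluate_battery(
    matrix: FeatureMatrix,
    battery: Sequence[ClassifierSpec] | None = None,
    k: int = 10,
    seed: int = 0,
) -> ClassifierReport:
    """Cross-validate every classifier on the full feature matrix.

    One shared stratified fold assignment; per-classifier out-of-fold
    predictions and class-A probabilities are pooled into MetricsRows.
    """
    battery = list(battery) if battery is not None else default_battery()
    names = [spec.name for spec in battery]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate classifier names in battery: {names}")
    X = matrix.values
    y = matrix.labels.astype(str)
    folds = stratified_kfold(y, k=k, seed=seed)
    rows = {}
    for spec in battery:
        y_pred = np.empty(len(y), dtype=object)
        prob_a = np.empty(len(y), dtype=np.float64)
        for test in folds:
            train = np.setdiff1d(np.arange(len(y)), test)
            est = spec.build(seed)
            if spec.standardize:
                est = make_pipeline(StandardScaler(), est)
            est.fit(X[train], y[train])
            y_pred[test] = est.predict(X[test])
            classes = list(est.classes_) if hasattr(est, "classes_") else list(
                est[-1].classes_
            )
            prob_a[test] = est.predict_proba(X[test])[:, classes.index("A")]
        try:
            rows[spec.name] = compute_metrics(y, y_pred.astype(str), prob_a, folds)
        except ValueError as exc:
            raise ValueError(f"{spec.name}: {exc}") from exc
    table = pd.DataFrame(
        {name: row.as_dict() for name, row in rows.items()}
    ).T[METRIC_COLUMNS]
    table.loc["Mean"] = table.mean(axis=0)
    return ClassifierReport(table=table, folds=folds, seed=seed, k=k)
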