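"""Classification of ROIs from texture features, ROC analysis, and
evaluation of a subjective binary rater.

Three models (binomial logistic regression, RBF-kernel support vector
machine, 100-tree random forest) are trained on a stratified 80/20
split. Features are standardized with training-set statistics only;
undefined values are imputed by the training-set median. Test accuracy
and the trapezoidal area under the ROC curve are reported per model.

A single binary rater yields one operating point; the conventional
two-segment ROC through it gives AUC = (sensitivity + specificity) / 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "ClassifierConfig",
    "ClassifierReport",
    "RaterEvaluation",
    "FEATURE_COLUMNS",
    "roc_auc",
    "train_and_evaluate",
    "evaluate_rater",
]

FEATURE_COLUMNS = ["ASM", "IDM", "CON", "COR", "SA", "SVAR", "EnLH", "EnHL", "EnHH"]

MODEL_NAMES = ("logistic_regression", "svm", "random_forest")


@dataclass(frozen=True)
class ClassifierConfig:
    """Model hyperparameters (the defaults are deliberately plain)."""

    test_fraction: float = 0.2
    svm_c: float = 1.0
    svm_gamma: str | float = "scale"
    lr_c: float = 1.0
    rf_trees: int = 100


@dataclass
class ClassifierReport:
    """Held-out performance of one model on one seeded split."""

    model: str
    accuracy: float
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    split_seed: int
    n_train: int
    n_test: int


@dataclass(frozen=True)
class RaterEvaluation:
    """Confusion counts and single-operating-point ROC of a binary rater."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def auc(self) -> float:
        return (self.sensitivity + self.specificity) / 2.0


def roc_auc(scores: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve (threshold sweep, ties grouped) and trapezoidal AUC.

    Equals the Mann–Whitney identity AUC = U / (n₁·n₂). Raises
    ``ValueError`` if truth has a single class.
    """
    truth = np.asarray(truth)
    if len(np.unique(truth)) < 2:
        raise ValueError("truth must contain both classes")
    fpr, tpr, _ = roc_curve(truth, np.asarray(scores, dtype=float))
    return fpr, tpr, float(_trapezoid_auc(fpr, tpr))


def _impute_median(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    med = np.nanmedian(train, axis=0)
    train = np.where(np.isnan(train), med, train)
    test = np.where(np.isnan(test), med, test)
    return train, test


def train_and_evaluate(
    features: pd.DataFrame,
    seed: int,
    config: ClassifierConfig = ClassifierConfig(),
) -> list[ClassifierReport]:
    """Fit and score the three models on one stratified 80/20 split.

    ``features`` must carry ``group`` plus the nine feature columns.
    Reports are bit-reproducible given (features, seed).
    """
    missing = [c for c in FEATURE_COLUMNS if c not in features.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    y = features["group"].to_numpy(dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    if counts.min() < 20:
        raise ValueError("need at least 20 ROIs per class to train and test")
    X = features[FEATURE_COLUMNS].to_numpy(dtype=float)

    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=config.test_fraction, random_state=seed, stratify=y
    )
    X_tr, X_te = _impute_median(X_tr, X_te)
    scaler = StandardScaler().fit(X_tr)
    X_tr = scaler.transform(X_tr)
    X_te = scaler.transform(X_te)

    models = {
        "logistic_regression": LogisticRegression(C=config.lr_c, max_iter=2000),
        "svm": SVC(kernel="rbf", C=config.svm_c, gamma=config.svm_gamma),
        "random_forest": RandomForestClassifier(
            n_estimators=config.rf_trees, random_state=seed
        ),
    }
    reports = []
    for name, model in models.items():
        model.fit(X_tr, y_tr)
        acc = float(np.mean(model.predict(X_te) == y_te))
        if name == "svm":
            scores = model.decision_function(X_te)  # continuous margin for ROC
        else:
            scores = model.predict_proba(X_te)[:, 1]
        fpr, tpr, area = roc_auc(scores, y_te)
        reports.append(
            ClassifierReport(
                model=name, accuracy=acc, fpr=fpr, tpr=tpr, auc=area,
                split_seed=seed, n_train=len(y_tr), n_test=len(y_te),
            )
        )
    return reports


def evaluate_rater(ratings: np.ndarray, truth: np.ndarray) -> RaterEvaluation:
    """Confusion table and single-point ROC for binary ratings vs truth."""
    ratings = np.asarray(ratings)
    truth = np.asarray(truth)
    if ratings.shape != truth.shape:
        raise ValueError("ratings and truth must have equal length")
    for arr, name in ((ratings, "ratings"), (truth, "truth")):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} must be binary (0/1)")
    tp = int(np.sum((ratings == 1) & (truth == 1)))
    fp = int(np.sum((ratings == 1) & (truth == 0)))
    tn = int(np.sum((ratings == 0) & (truth == 0)))
    fn = int(np.sum((ratings == 0) & (truth == 1)))
    return RaterEvaluation(tp=tp, fp=fp, tn=tn, fn=fn)


def evaluate_rater_table(table: pd.DataFrame) -> RaterEvaluation:
    """Evaluate a rater from a CSV-backed table with ``rating``/``truth``."""
    return evaluate_rater(table["rating"].to_numpy(), table["truth"].to_numpy())
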