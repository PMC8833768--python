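"""Patient-level BCa-vs-ND classification from events/mL profiles.

Each individual is a 12-dimensional vector of per-category events/mL
(the derived totals are linear combinations and are excluded).  Three
model families — random forest (RF), RBF support vector machine (SVM)
and Gaussian naive Bayes (NB) — are evaluated by stratified 5-fold
cross-validation; RF and SVM tune hyperparameters by an inner grid
search on each training split.  Reported metrics are per-fold and
mean +/- SD accuracy, sensitivity (BCa as the positive class),
specificity and ROC AUC, plus pooled misclassification counts by group
and, for RF, impurity-based feature importances averaged across folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .categories import RARE_CATEGORIES
from .enumeration import CohortDataset

__all__ = [
    "ModelReport",
    "DEFAULT_GRIDS",
    "build_design_matrix",
    "crossval_models",
    "feature_importance",
    "summarize",
]

FAMILIES = ("RF", "SVM", "NB")

DEFAULT_GRIDS: dict[str, dict] = {
    "RF": {"n_estimators": [100, 250], "max_depth": [None, 5, 10]},
    "SVM": {"svc__C": [0.1, 1.0, 10.0, 100.0], "svc__gamma": ["scale", 0.01, 0.1]},
}

METRICS = ("accuracy", "sensitivity", "specificity", "auc")


@dataclass
class ModelReport:
    """Cross-validation report for one model family."""

    family: str
    seed: int
    fold_assignments: np.ndarray  # fold index per individual
    per_fold: dict[str, list[float]]  # metric -> 5 values
    misclassified: dict[str, int]  # pooled, by true group
    feature_importances: np.ndarray | None = None  # RF only
    feature_names: list[str] = field(default_factory=list)
    best_params: list[dict] = field(default_factory=list)

    def mean(self, metric: str) -> float:
        return float(np.mean(self.per_fold[metric]))

    def sd(self, metric: str) -> float:
        return float(np.std(self.per_fold[metric], ddof=1))

    @property
    def total_misclassified(self) -> int:
        return sum(self.misclassified.values())


def build_design_matrix(cohort: CohortDataset) -> tuple[pd.DataFrame, np.ndarray]:
    """(feature matrix, labels) with BCa encoded 1 and ND 0.

    Columns are the 12 rare categories in canonical order, so matrices
    are identical across runs for the same cohort.
    """
    df = cohort.to_frame()
    missing = [c for c in RARE_CATEGORIES if c not in df.columns]
    if missing:
        raise ValueError(f"profiles missing categories: {missing}")
    x = df[list(RARE_CATEGORIES)].copy()
    x.index = df["sample_id"]
    y = (df["group"] == "BCa").to_numpy(dtype=int)
    return x, y


def _make_model(family: str, grids: dict[str, dict], seed: int):
    if family == "RF":
        base = RandomForestClassifier(random_state=seed)
        return GridSearchCV(base, grids["RF"], cv=3, scoring="accuracy", n_jobs=1)
    if family == "SVM":
        pipe = Pipeline(
            [("scale", StandardScaler()), ("svc", SVC(kernel="rbf", random_state=seed))]
        )
        return GridSearchCV(pipe, grids["SVM"], cv=3, scoring="accuracy", n_jobs=1)
    if family == "NB":
        return GaussianNB()
    raise ValueError(f"unknown model family: {family}")


def _scores(model, x_test: np.ndarray) -> np.ndarray:
    est = model.best_estimator_ if isinstance(model, GridSearchCV) else model
    if hasattr(est, "predict_proba"):
        return est.predict_proba(x_test)[:, 1]
    return est.decision_function(x_test)


def crossval_models(
    matrix: pd.DataFrame,
    labels: np.ndarray,
    seed: int = 0,
    grids: dict[str, dict] | None = None,
    families: tuple[str, ...] = FAMILIES,
    n_folds: int = 5,
) -> list[ModelReport]:
    """Stratified k-fold cross-validation of the requested families.

    Fold assignment is shared across families and reproducible under
    ``seed``.  With a cohort size not divisible by ``n_folds`` the
    folds are made as equal as possible (with a warning).
    """
    x = np.asarray(matrix, dtype=float)
    y = np.asarray(labels, dtype=int)
    names = (
        list(matrix.columns) if isinstance(matrix, pd.DataFrame)
        else [f"f{i}" for i in range(x.shape[1])]
    )
    for cls in (0, 1):
        if (y == cls).sum() < n_folds:
            raise ValueError("need at least n_folds individuals per class")
    if len(y) % n_folds:
        warnings.warn(
            f"cohort of {len(y)} not divisible into {n_folds} equal folds; "
            "using nearest-equal sizes",
            stacklevel=2,
        )
    grids = grids or DEFAULT_GRIDS
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    splits = list(skf.split(x, y))
    assignment = np.empty(len(y), dtype=int)
    for fold, (_, test_idx) in enumerate(splits):
        assignment[test_idx] = fold

    reports = []
    for family in families:
        per_fold: dict[str, list[float]] = {m: [] for m in METRICS}
        mis = {"BCa": 0, "ND": 0}
        importances = []
        best_params: list[dict] = []
        for train_idx, test_idx in splits:
            model = _make_model(family, grids, seed)
            model.fit(x[train_idx], y[train_idx])
            pred = model.predict(x[test_idx])
            truth = y[test_idx]
            scores = _scores(model, x[test_idx])
            tp = int(((pred == 1) & (truth == 1)).sum())
            tn = int(((pred == 0) & (truth == 0)).sum())
            fp = int(((pred == 1) & (truth == 0)).sum())
            fn = int(((pred == 0) & (truth == 1)).sum())
            per_fold["accuracy"].append((tp + tn) / len(truth))
            per_fold["sensitivity"].append(tp / (tp + fn) if tp + fn else np.nan)
            per_fold["specificity"].append(tn / (tn + fp) if tn + fp else np.nan)
            per_fold["auc"].append(float(roc_auc_score(truth, scores)))
            mis["BCa"] += fn
            mis["ND"] += fp
            if isinstance(model, GridSearchCV):
                best_params.append(dict(model.best_params_))
            if family == "RF":
                importances.append(model.best_estimator_.feature_importances_)
        report = ModelReport(
            family=family,
            seed=seed,
            fold_assignments=assignment,
            per_fold=per_fold,
            misclassified=mis,
            feature_names=names,
            best_params=best_params,
        )
        if importances:
            imp = np.mean(importances, axis=0)
            report.feature_importances = imp / imp.sum()
        reports.append(report)
    return reports


def feature_importance(reports: list[ModelReport] | ModelReport) -> pd.Series:
    """Averaged RF feature importances, ranked descending (sum = 1)."""
    if isinstance(reports, ModelReport):
        reports = [reports]
    rf = [r for r in reports if r.family == "RF"]
    if not rf:
        raise ValueError("feature importance requires a random-forest report")
    imp = np.mean([r.feature_importances for r in rf], axis=0)
    imp = imp / imp.sum()
    return pd.Series(imp, index=rf[0].feature_names).sort_values(ascending=False)


def summarize(reports: list[ModelReport]) -> pd.DataFrame:
    """Mean +/- SD metric table per model family with pooled errors."""
    if not reports:
        raise ValueError("no reports to summarize")
    rows = []
    for r in reports:
        row = {"family": r.family}
        for m in METRICS:
            row[f"{m}_mean"] = r.mean(m)
            row[f"{m}_sd"] = r.sd(m)
        row["misclassified_total"] = r.total_misclassified
        row["misclassified_BCa"] = r.misclassified["BCa"]
        row["misclassified_ND"] = r.misclassified["ND"]
        rows.append(row)
    return pd.DataFrame(rows)
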