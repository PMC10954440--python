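"""Folding-status classification and folding-strength regression.

Two model families share one protocol: a seeded stratified (classifier) or
plain (regressor) hold-out split, exhaustive grid search under 5-fold
cross-validation on the training & validation part, a final refit on all
of it, and hold-out evaluation.  Model selection uses mean AUROC across
folds for classification and mean R² for regression.

The module is organised around Model objects fitted into Results objects:

>>> model = FoldingClassifier(X_train, y_train, seed=0)
>>> res = model.fit()          # CV grid search + final refit
>>> res.evaluate(X_test, y_test).summary()

``FoldingClassifier`` wraps the in-package balanced random forest (or a
plain random forest baseline); ``StrengthRegressor`` wraps gradient-
boosted regression trees, whose impurity-gain importances feed the
feature-importance report grouped by the sign of each feature's marginal
Pearson correlation with the target.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.ensemble import GradientBoostingRegressor, RandomForestClassifier
from sklearn.metrics import (
    mean_absolute_error,
    mean_squared_error,
    r2_score,
    roc_auc_score,
)
from sklearn.model_selection import KFold, ParameterGrid, StratifiedKFold, train_test_split

from .ensemble import BalancedRandomForestClassifier
from .features import FEATURE_NAMES, SCHEMA_VERSION

logger = logging.getLogger(__name__)

DEFAULT_CLASSIFIER_GRID: dict[str, list] = {
    "n_estimators": [100, 300],
    "max_depth": [4, 8, None],
}
DEFAULT_REGRESSOR_GRID: dict[str, list] = {
    "n_estimators": [100, 300],
    "max_depth": [2, 4],
    "learning_rate": [0.05, 0.1, 0.3],
}


def split_dataset(
    X,
    y,
    test_fraction: float,
    seed: int,
    stratify: bool = True,
):
    """Seeded hold-out split; stratified by label for classification."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0,1)")
    y = np.asarray(y)
    strat = y if stratify else None
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=test_fraction, random_state=seed, stratify=strat
    )
    if stratify and (min(np.bincount(y_tr.astype(int))) < 2):
        raise ValueError("fewer than 2 rows per class after split")
    return X_tr, X_te, y_tr, y_te


def _classification_metrics(y_true, y_pred, y_score) -> dict[str, float]:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    recall = tp / (tp + fn) if tp + fn else float("nan")
    specificity = tn / (tn + fp) if tn + fp else float("nan")
    out = {
        "accuracy": (tp + tn) / len(y_true),
        "recall": recall,
        "specificity": specificity,
        "balanced_accuracy": (recall + specificity) / 2.0,
    }
    if len(np.unique(y_true)) < 2:
        out["auroc"] = float("nan")  # undefined on a single-class set
    else:
        out["auroc"] = float(roc_auc_score(y_true, y_score))
    return out


def _regression_metrics(y_true, y_pred) -> dict[str, float]:
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if len(y_true) > 1 and np.ptp(y_true) > 0 and np.ptp(y_pred) > 0:
        pcc = float(stats.pearsonr(y_true, y_pred)[0])
    else:
        pcc = float("nan")  # undefined for constant inputs
    return {
        "r2": float(r2_score(y_true, y_pred)),
        "rmse": float(np.sqrt(mean_squared_error(y_true, y_pred))),
        "mae": float(mean_absolute_error(y_true, y_pred)),
        "pcc": pcc,
    }


@dataclass
class EvalReport:
    """Metric bundle for one evaluation (classification or regression)."""

    task: str
    metrics: dict[str, float]
    n: int

    def summary(self) -> str:
        lines = [f"{self.task} evaluation (n={self.n})", "-" * 34]
        for k, v in self.metrics.items():
            lines.append(f"{k:>20s}: {v:.4f}")
        return "\n".join(lines)

    def __getitem__(self, key: str) -> float:
        return self.metrics[key]


def cv_grid_search(
    make_estimator,
    grid: Mapping[str, Sequence],
    X,
    y,
    folds: int = 5,
    scoring: str = "auroc",
    seed: int = 0,
    classification: bool = True,
) -> tuple[dict, pd.DataFrame]:
    """Exhaustive grid search under seeded k-fold CV.

    Returns (best parameter dict, full CV table with one row per
    (params, fold) and the per-combination mean).  Degenerate folds whose
    training part holds a single class are skipped with a warning.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    combos = list(ParameterGrid(dict(grid)))
    if not combos:
        raise ValueError("empty hyperparameter grid")
    splitter = (
        StratifiedKFold(folds, shuffle=True, random_state=seed)
        if classification
        else KFold(folds, shuffle=True, random_state=seed)
    )
    split_args = (X, y) if classification else (X,)
    fold_idx = list(splitter.split(*split_args)) if classification else list(
        splitter.split(X)
    )

    rows = []
    for pi, params in enumerate(combos):
        for fi, (tr, va) in enumerate(fold_idx):
            if classification and len(np.unique(y[tr])) < 2:
                logger.warning("fold %d has a single training class; skipped", fi)
                continue
            est = make_estimator(params, seed)
            est.fit(X[tr], y[tr])
            if classification:
                score = est.predict_proba(X[va])[:, 1]
                m = _classification_metrics(y[va], est.predict(X[va]), score)
            else:
                m = _regression_metrics(y[va], est.predict(X[va]))
            rows.append({"params_id": pi, "fold": fi, **params, **m})
    table = pd.DataFrame(rows)
    means = table.groupby("params_id")[scoring].mean()
    best_id = int(means.idxmax())
    return dict(combos[best_id]), table


@dataclass
class _ResultsBase:
    model: Any
    best_params: dict
    cv_table: pd.DataFrame
    seed: int
    task: str = field(init=False, default="")
    feature_names: tuple[str, ...] = FEATURE_NAMES
    schema_version: str = SCHEMA_VERSION

    def predict(self, X):
        self._check_schema(X)
        return self.model.predict(np.asarray(X, dtype=float))

    def _check_schema(self, X) -> None:
        if np.asarray(X).shape[1] != len(self.feature_names):
            raise ValueError(
                f"feature-count mismatch: model expects {len(self.feature_names)}"
            )

    def save(self, path) -> None:
        joblib.dump(
            {
                "task": self.task,
                "model": self.model,
                "best_params": self.best_params,
                "cv_table": self.cv_table,
                "seed": self.seed,
                "feature_names": self.feature_names,
                "schema_version": self.schema_version,
            },
            path,
        )

    def summary(self) -> str:
        scoring = "auroc" if self.task == "classification" else "r2"
        cv_mean = (
            self.cv_table.groupby("params_id")[scoring].mean().max()
            if len(self.cv_table)
            else float("nan")
        )
        lines = [
            f"{self.task} model ({type(self.model).__name__})",
            "-" * 40,
            f"selected hyperparameters: {self.best_params}",
            f"mean CV {scoring}: {cv_mean:.4f}",
            f"seed: {self.seed}  schema: {self.schema_version}",
        ]
        return "\n".join(lines)


def load_results(path) -> "FoldingClassifierResults | StrengthRegressorResults":
    payload = joblib.load(path)
    cls = (
        FoldingClassifierResults
        if payload["task"] == "classification"
        else StrengthRegressorResults
    )
    res = cls(
        model=payload["model"],
        best_params=payload["best_params"],
        cv_table=payload["cv_table"],
        seed=payload["seed"],
    )
    res.feature_names = tuple(payload["feature_names"])
    res.schema_version = payload["schema_version"]
    if res.schema_version != SCHEMA_VERSION:
        raise ValueError(
            f"model schema {res.schema_version!r} != expected {SCHEMA_VERSION!r}"
        )
    return res


@dataclass
class FoldingClassifierResults(_ResultsBase):
    def __post_init__(self) -> None:
        self.task = "classification"

    def predict_proba(self, X):
        self._check_schema(X)
        return self.model.predict_proba(np.asarray(X, dtype=float))

    def evaluate(self, X_test, y_test) -> EvalReport:
        self._check_schema(X_test)
        X_test = np.asarray(X_test, dtype=float)
        score = self.model.predict_proba(X_test)[:, 1]
        m = _classification_metrics(y_test, self.model.predict(X_test), score)
        return EvalReport("classification", m, len(np.asarray(y_test)))


@dataclass
class StrengthRegressorResults(_ResultsBase):
    def __post_init__(self) -> None:
        self.task = "regression"

    def evaluate(self, X_test, y_test) -> EvalReport:
        self._check_schema(X_test)
        m = _regression_metrics(y_test, self.model.predict(np.asarray(X_test, dtype=float)))
        return EvalReport("regression", m, len(np.asarray(y_test)))


class FoldingClassifier:
    """Folding-status model: balanced random forest or plain-RF baseline.

    ``fit()`` runs the 5-fold CV grid search (selection by mean AUROC),
    refits the winner on all training data and returns a Results object.
    """

    def __init__(
        self,
        X,
        y,
        algorithm: str = "balanced_rf",
        grid: Mapping[str, Sequence] | None = None,
        seed: int = 0,
    ):
        if algorithm not in ("balanced_rf", "rf"):
            raise ValueError(f"unknown algorithm {algorithm!r}")
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y).astype(int)
        if len(np.unique(self.y)) < 2:
            raise ValueError("training data holds a single class")
        self.algorithm = algorithm
        self.grid = dict(grid) if grid is not None else dict(DEFAULT_CLASSIFIER_GRID)
        self.seed = seed

    def _make(self, params: dict, seed: int):
        if self.algorithm == "balanced_rf":
            return BalancedRandomForestClassifier(random_state=seed, **params)
        return RandomForestClassifier(random_state=seed, **params)

    def fit(self, folds: int = 5) -> FoldingClassifierResults:
        best, table = cv_grid_search(
            self._make, self.grid, self.X, self.y,
            folds=folds, scoring="auroc", seed=self.seed, classification=True,
        )
        final = self._make(best, self.seed).fit(self.X, self.y)
        return FoldingClassifierResults(
            model=final, best_params=best, cv_table=table, seed=self.seed
        )


class StrengthRegressor:
    """Folding-strength model: gradient-boosted regression trees.

    Selection criterion is mean CV R²; ``fit()`` returns Results carrying
    the fitted booster, the CV table and the gain-based importances.
    """

    def __init__(
        self,
        X,
        y,
        grid: Mapping[str, Sequence] | None = None,
        seed: int = 0,
    ):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.grid = dict(grid) if grid is not None else dict(DEFAULT_REGRESSOR_GRID)
        self.seed = seed

    def _make(self, params: dict, seed: int):
        return GradientBoostingRegressor(random_state=seed, **params)

    def fit(self, folds: int = 5) -> StrengthRegressorResults:
        best, table = cv_grid_search(
            self._make, self.grid, self.X, self.y,
            folds=folds, scoring="r2", seed=self.seed, classification=False,
        )
        final = self._make(best, self.seed).fit(self.X, self.y)
        return StrengthRegressorResults(
            model=final, best_params=best, cv_table=table, seed=self.seed
        )


def feature_importance(
    results: _ResultsBase, X_train, y_train, top: int = 10
) -> pd.DataFrame:
    """Gain importances annotated with marginal Pearson-correlation signs.

    Each feature's importance is the ensemble's gain (impurity-reduction)
    attribution; its sign is that of the feature's marginal Pearson
    correlation with the target on the training set, splitting the ranking
    into a stabilising (positive) and a destabilising (negative) group.
    """
    model = results.model
    if not hasattr(model, "feature_importances_"):
        raise TypeError("feature importance requires a tree-ensemble model")
    imp = np.asarray(model.feature_importances_, dtype=float)
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    signs = []
    pccs = []
    for j in range(X_train.shape[1]):
        col = X_train[:, j]
        if np.ptp(col) == 0 or np.ptp(y_train) == 0:
            r = 0.0
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r = float(stats.pearsonr(col, y_train)[0])
            if np.isnan(r):
                r = 0.0
        pccs.append(r)
        signs.append("positive" if r >= 0 else "negative")
    table = pd.DataFrame(
        {
            "feature": list(results.feature_names),
            "importance": imp,
            "pcc": pccs,
            "sign": signs,
        }
    ).sort_values("importance", ascending=False, ignore_index=True)
    table["rank_in_group"] = table.groupby("sign").cumcount() + 1
    table["top_group"] = table["rank_in_group"] <= top
    return table
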