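"""Barcode reader: preprocessing, model comparison, tuning and evaluation.

Fingerprint tables (14 features per particle, ``label`` column with barcode
ids) are Z-score standardized with training-set statistics, fifteen
classifier families are compared under stratified 10-fold cross-validation
and sorted on mean accuracy, the top family is tuned by random search over a
small per-family grid, and the tuned model is evaluated on a stratified
held-out test set via its confusion matrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
import yaml
from sklearn.base import clone
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.ensemble import (
    AdaBoostClassifier,
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression, RidgeClassifier
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .localize import FEATURE_COLUMNS

__all__ = [
    "Standardizer",
    "ConfusionMatrix",
    "Leaderboard",
    "ReaderModel",
    "MODEL_FAMILIES",
    "DEFAULT_ROSTER",
    "make_classifier",
    "stratified_split",
    "compare_models",
    "tune_top",
    "fit_family",
    "evaluate",
    "predict",
]

logger = logging.getLogger(__name__)


class Standardizer:
    """Per-feature Z-score transform learned on training data.

    Constant features (sd 0) are mapped to exactly 0 instead of NaN.
    """

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "Standardizer":
        X = np.asarray(X, dtype=float)
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        self.scale_ = np.where(sd > 0, sd, 1.0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("standardizer not fitted")
        return (np.asarray(X, dtype=float) - self.mean_) / self.scale_

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)


def _lgbm(seed: int, **kw):
    from lightgbm import LGBMClassifier

    kw.setdefault("n_estimators", 100)
    return LGBMClassifier(random_state=seed, verbose=-1, n_jobs=1, **kw)


#: The fifteen classifier families of the comparison roster (six linear,
#: nine non-linear), keyed by short name.
MODEL_FAMILIES: dict[str, callable] = {
    "mlp": lambda seed, **kw: MLPClassifier(random_state=seed, max_iter=400, **kw),
    "lightgbm": _lgbm,
    "random_forest": lambda seed, **kw: RandomForestClassifier(random_state=seed, n_jobs=1, **kw),
    "extra_trees": lambda seed, **kw: ExtraTreesClassifier(random_state=seed, n_jobs=1, **kw),
    "svm_rbf": lambda seed, **kw: SVC(kernel="rbf", random_state=seed, **kw),
    "svm_linear": lambda seed, **kw: SVC(kernel="linear", random_state=seed, **kw),
    "logistic_regression": lambda seed, **kw: LogisticRegression(
        max_iter=1000, random_state=seed, **kw
    ),
    "knn": lambda seed, **kw: KNeighborsClassifier(**kw),
    "decision_tree": lambda seed, **kw: DecisionTreeClassifier(random_state=seed, **kw),
    "lda": lambda seed, **kw: LinearDiscriminantAnalysis(**kw),
    "ridge": lambda seed, **kw: RidgeClassifier(**kw),
    "naive_bayes": lambda seed, **kw: GaussianNB(**kw),
    "qda": lambda seed, **kw: QuadraticDiscriminantAnalysis(**kw),
    "adaboost": lambda seed, **kw: AdaBoostClassifier(random_state=seed, **kw),
    "gradient_boosting": lambda seed, **kw: GradientBoostingClassifier(random_state=seed, **kw),
}

DEFAULT_ROSTER = tuple(MODEL_FAMILIES)

#: Families whose fitted trees expose split-gain feature importances.
TREE_ENSEMBLE_FAMILIES = ("lightgbm", "gradient_boosting", "random_forest", "extra_trees")

#: Random-search grids for :func:`tune_top`.  The perceptron grid includes
#: hidden-layer width doubling and constant vs adaptive learning rates.
TUNING_GRIDS: dict[str, dict[str, list]] = {
    "mlp": {
        "hidden_layer_sizes": [(50,), (100,), (200,), (100, 100), (200, 200)],
        "learning_rate": ["constant", "adaptive"],
        "alpha": [1e-4, 1e-3, 1e-2],
    },
    "lightgbm": {
        "n_estimators": [50, 100, 200],
        "learning_rate": [0.05, 0.1, 0.2],
        "num_leaves": [15, 31, 63],
    },
    "random_forest": {
        "n_estimators": [100, 200],
        "max_features": ["sqrt", None],
        "min_samples_leaf": [1, 2, 5],
    },
    "extra_trees": {
        "n_estimators": [100, 200],
        "max_features": ["sqrt", None],
        "min_samples_leaf": [1, 2, 5],
    },
    "svm_rbf": {"C": [0.1, 1.0, 10.0], "gamma": ["scale", 0.1, 0.01]},
    "svm_linear": {"C": [0.1, 1.0, 10.0]},
    "logistic_regression": {"C": [0.1, 1.0, 10.0]},
    "knn": {"n_neighbors": [3, 5, 9, 15], "weights": ["uniform", "distance"]},
    "decision_tree": {"max_depth": [None, 5, 10, 20], "min_samples_leaf": [1, 2, 5]},
    "lda": {"solver": ["svd", "lsqr"]},
    "ridge": {"alpha": [0.1, 1.0, 10.0]},
    "naive_bayes": {"var_smoothing": [1e-9, 1e-8, 1e-7]},
    "qda": {"reg_param": [0.0, 0.01, 0.1]},
    "adaboost": {"n_estimators": [50, 100], "learning_rate": [0.5, 1.0]},
    "gradient_boosting": {"n_estimators": [50, 100], "learning_rate": [0.05, 0.1]},
}


def make_classifier(family: str, seed: int, **hyperparams):
    if family not in MODEL_FAMILIES:
        raise ValueError(f"unknown model family {family!r}")
    return MODEL_FAMILIES[family](seed, **hyperparams)


@dataclass
class ConfusionMatrix:
    """K x K counts (rows true, cols predicted) with derived metrics.

    Per-class precision is TP/(TP+FP) with the convention that classes
    never predicted get precision 0; sensitivity is per-class recall
    TP/(TP+FN).  Reported macro values average over classes.
    """

    counts: np.ndarray
    classes: np.ndarray

    @classmethod
    def from_predictions(cls, y_true, y_pred, classes) -> "ConfusionMatrix":
        classes = np.asarray(classes)
        counts = _sk_confusion(y_true, y_pred, labels=classes)
        return cls(counts=counts, classes=classes)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts) / max(self.total, 1))

    @property
    def precision_per_class(self) -> np.ndarray:
        col = self.counts.sum(axis=0)
        tp = np.diag(self.counts)
        return np.where(col > 0, tp / np.maximum(col, 1), 0.0)

    @property
    def sensitivity_per_class(self) -> np.ndarray:
        row = self.counts.sum(axis=1)
        tp = np.diag(self.counts)
        return np.where(row > 0, tp / np.maximum(row, 1), 0.0)

    @property
    def macro_precision(self) -> float:
        return float(self.precision_per_class.mean())

    @property
    def macro_sensitivity(self) -> float:
        return float(self.sensitivity_per_class.mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.classes, columns=self.classes)


@dataclass
class Leaderboard:
    """Cross-validation scores per family, sorted on mean accuracy."""

    table: pd.DataFrame  # columns: family, accuracy, precision, sensitivity
    fold_scores: dict[str, list[float]]

    @property
    def best_family(self) -> str:
        return str(self.table.iloc[0]["family"])


@dataclass
class ReaderModel:
    """A trained barcode reader: standardizer + fitted classifier + roster."""

    standardizer: Standardizer
    classifier: object
    family: str
    hyperparams: dict
    classes: np.ndarray
    feature_columns: list[str]
    seed: int
    folds: int
    cv_accuracy: float | None = None

    def feature_matrix(self, table: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.feature_columns if c not in table.columns]
        if missing:
            raise ValueError(f"feature table is missing columns: {missing}")
        return table[self.feature_columns].to_numpy(dtype=float)

    def predict_labels(self, table: pd.DataFrame) -> np.ndarray:
        X = self.feature_matrix(table)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return self.classifier.predict(self.standardizer.transform(X))

    def save(self, path) -> None:
        joblib.dump(self, str(path))
        manifest = {
            "family": self.family,
            "hyperparams": {k: repr(v) for k, v in self.hyperparams.items()},
            "classes": [int(c) for c in self.classes],
            "features": list(self.feature_columns),
            "seed": int(self.seed),
            "folds": int(self.folds),
            "cv_accuracy": None if self.cv_accuracy is None else float(self.cv_accuracy),
        }
        with open(str(path) + ".yaml", "w") as fh:
            yaml.safe_dump(manifest, fh)

    @staticmethod
    def load(path) -> "ReaderModel":
        return joblib.load(str(path))


def _xy(table: pd.DataFrame, feature_columns) -> tuple[np.ndarray, np.ndarray]:
    X = table[list(feature_columns)].to_numpy(dtype=float)
    y = table["label"].to_numpy()
    return X, y


def stratified_split(
    table: pd.DataFrame, test_fraction: float = 0.2, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified train/test split preserving class imbalance (default 80/20)."""
    counts = table["label"].value_counts()
    small = counts[counts < 2]
    if len(small):
        raise ValueError(
            f"classes with fewer than 2 records cannot be split: {sorted(small.index.tolist())}"
        )
    train, test = train_test_split(
        table,
        test_size=test_fraction,
        stratify=table["label"],
        random_state=seed,
    )
    return train.reset_index(drop=True), test.reset_index(drop=True)


def _cv_scores(
    X: np.ndarray, y: np.ndarray, family: str, folds: int, seed: int, **hyperparams
) -> dict[str, list[float]]:
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    acc, prec, sens = [], [], []
    for tr, va in skf.split(X, y):
        std = Standardizer().fit(X[tr])
        clf = make_classifier(family, seed, **hyperparams)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(std.transform(X[tr]), y[tr])
            pred = clf.predict(std.transform(X[va]))
        pred = np.asarray(pred)
        cm = ConfusionMatrix.from_predictions(y[va], pred, np.unique(y))
        acc.append(cm.accuracy)
        prec.append(cm.macro_precision)
        sens.append(cm.macro_sensitivity)
    return {"accuracy": acc, "precision": prec, "sensitivity": sens}


def compare_models(
    train: pd.DataFrame,
    roster: tuple[str, ...] = DEFAULT_ROSTER,
    folds: int = 10,
    seed: int = 0,
    feature_columns: list[str] | None = None,
) -> Leaderboard:
    """Cross-validate every family at library defaults; sort on accuracy.

    A family that fails to fit is recorded with score 0 and a logged
    warning rather than aborting the comparison.
    """
    if not roster:
        raise ValueError("roster must be nonempty")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    feature_columns = list(FEATURE_COLUMNS) if feature_columns is None else feature_columns
    X, y = _xy(train, feature_columns)
    rows, fold_scores = [], {}
    for family in roster:
        try:
            scores = _cv_scores(X, y, family, folds, seed)
            rows.append(
                {
                    "family": family,
                    "accuracy": float(np.mean(scores["accuracy"])),
                    "precision": float(np.mean(scores["precision"])),
                    "sensitivity": float(np.mean(scores["sensitivity"])),
                }
            )
            fold_scores[family] = scores["accuracy"]
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning("family %s failed to fit: %s", family, exc)
            rows.append({"family": family, "accuracy": 0.0, "precision": 0.0, "sensitivity": 0.0})
            fold_scores[family] = []
    table = (
        pd.DataFrame(rows)
        .sort_values("accuracy", ascending=False, kind="mergesort")
        .reset_index(drop=True)
    )
    return Leaderboard(table=table, fold_scores=fold_scores)


def _sample_grid(grid: dict[str, list], budget: int, rng: np.random.Generator) -> list[dict]:
    """Default config first, then distinct random grid draws up to budget."""
    candidates: list[dict] = [{}]
    seen = {()}
    tries = 0
    while len(candidates) < budget and tries < budget * 50:
        tries += 1
        cand = {k: v[rng.integers(len(v))] for k, v in grid.items()}
        key = tuple(sorted((k, repr(v)) for k, v in cand.items()))
        if key not in seen:
            seen.add(key)
            candidates.append(cand)
    return candidates


def tune_top(
    train: pd.DataFrame,
    family: str,
    budget: int = 10,
    seed: int = 0,
    folds: int = 10,
    feature_columns: list[str] | None = None,
) -> ReaderModel:
    """Random search over a small per-family grid; returns the best model.

    The library-default configuration is always the first candidate, so the
    tuned cross-validation accuracy never falls below the untuned one.  The
    winning configuration is refitted on the full training table.
    """
    if family not in MODEL_FAMILIES:
        raise ValueError(f"unknown model family {family!r}")
    if budget < 1:
        raise ValueError("budget must be >= 1")
    feature_columns = list(FEATURE_COLUMNS) if feature_columns is None else feature_columns
    X, y = _xy(train, feature_columns)
    rng = np.random.default_rng(seed)
    grid = TUNING_GRIDS.get(family, {})
    candidates = _sample_grid(grid, budget, rng) if grid else [{}]
    best_params, best_acc = {}, -1.0
    for cand in candidates:
        acc = float(np.mean(_cv_scores(X, y, family, folds, seed, **cand)["accuracy"]))
        if acc > best_acc:
            best_acc, best_params = acc, cand
    std = Standardizer().fit(X)
    clf = make_classifier(family, seed, **best_params)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(std.transform(X), y)
    return ReaderModel(
        standardizer=std,
        classifier=clf,
        family=family,
        hyperparams=best_params,
        classes=np.unique(y),
        feature_columns=feature_columns,
        seed=seed,
        folds=folds,
        cv_accuracy=best_acc,
    )


def fit_family(
    train: pd.DataFrame,
    family: str,
    seed: int = 0,
    feature_columns: list[str] | None = None,
    **hyperparams,
) -> ReaderModel:
    """Fit one family at given (default) hyperparameters, no tuning."""
    feature_columns = list(FEATURE_COLUMNS) if feature_columns is None else feature_columns
    X, y = _xy(train, feature_columns)
    std = Standardizer().fit(X)
    clf = make_classifier(family, seed, **hyperparams)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(std.transform(X), y)
    return ReaderModel(
        standardizer=std,
        classifier=clf,
        family=family,
        hyperparams=hyperparams,
        classes=np.unique(y),
        feature_columns=feature_columns,
        seed=seed,
        folds=0,
    )


def evaluate(model: ReaderModel, test: pd.DataFrame) -> ConfusionMatrix:
    """Confusion matrix of the model on a labeled test table."""
    unseen = set(test["label"].unique()) - set(model.classes.tolist())
    if unseen:
        raise ValueError(f"test set contains classes outside the roster: {sorted(unseen)}")
    pred = model.predict_labels(test)
    return ConfusionMatrix.from_predictions(test["label"].to_numpy(), pred, model.classes)


def predict(model: ReaderModel, table: pd.DataFrame) -> tuple[np.ndarray, pd.Series]:
    """Predicted class per record plus the class-frequency histogram."""
    if len(table) == 0:
        hist = pd.Series(0, index=pd.Index(model.classes, name="label"))
        return np.array([], dtype=model.classes.dtype), hist
    pred = model.predict_labels(table)
    hist = (
        pd.Series(pred)
        .value_counts()
        .reindex(model.classes, fill_value=0)
        .rename_axis("label")
    )
    return pred, hist
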