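"""Experiments around the barcode reader.

Backward class elimination (accuracy vs number of barcodes), Y-scrambling
(label-permutation control), gain-based feature importance with a feature
ablation curve, a learning curve over observations per class, PCA
fingerprint visualization, and virtual-mixture evaluation on held-out data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .localize import FEATURE_COLUMNS
from .reader import (
    ConfusionMatrix,
    ReaderModel,
    TREE_ENSEMBLE_FAMILIES,
    compare_models,
    evaluate,
    fit_family,
    predict,
    stratified_split,
    tune_top,
)

__all__ = [
    "EliminationStep",
    "EliminationTrace",
    "PcaResult",
    "MixtureSpec",
    "backward_eliminate",
    "y_scramble",
    "feature_importance",
    "feature_ablation_curve",
    "learning_curve",
    "pca_fingerprint",
    "make_mixture",
    "evaluate_mixture",
]


def _child_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


@dataclass
class EliminationStep:
    remaining: list[int]
    dropped: int
    family: str
    accuracy: float
    macro_precision: float
    macro_sensitivity: float
    per_class_precision: dict[int, float]


@dataclass
class EliminationTrace:
    steps: list[EliminationStep]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_classes": [len(s.remaining) for s in self.steps],
                "dropped": [s.dropped for s in self.steps],
                "family": [s.family for s in self.steps],
                "accuracy": [s.accuracy for s in self.steps],
                "macro_precision": [s.macro_precision for s in self.steps],
                "macro_sensitivity": [s.macro_sensitivity for s in self.steps],
            }
        )

    def accuracy_at(self, n_classes: int) -> float:
        for s in self.steps:
            if len(s.remaining) == n_classes:
                return s.accuracy
        raise KeyError(f"no iteration with {n_classes} classes")


def backward_eliminate(
    table: pd.DataFrame,
    roster: tuple[str, ...],
    seed: int = 0,
    folds: int = 10,
    budget: int = 10,
    test_fraction: float = 0.2,
    feature_columns: list[str] | None = None,
) -> EliminationTrace:
    """Drop the worst-precision class and retrain, down to a single class.

    Every iteration re-splits, re-compares the roster, re-tunes the top
    family and evaluates on its test split; the class with the minimal
    per-class precision (ties: lowest id) is then removed.  With K0 starting
    classes the trace has K0 iterations; the final single-class iteration is
    trivially perfect.
    """
    classes = sorted(int(c) for c in table["label"].unique())
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to eliminate")
    rng = np.random.default_rng(seed)
    steps: list[EliminationStep] = []
    remaining = classes
    while remaining:
        sub = table[table["label"].isin(remaining)]
        if len(remaining) == 1:
            steps.append(
                EliminationStep(
                    remaining=list(remaining),
                    dropped=remaining[0],
                    family="trivial",
                    accuracy=1.0,
                    macro_precision=1.0,
                    macro_sensitivity=1.0,
                    per_class_precision={remaining[0]: 1.0},
                )
            )
            break
        it_seed = _child_seed(rng)
        train, test = stratified_split(sub, test_fraction, it_seed)
        board = compare_models(train, roster, folds, it_seed, feature_columns)
        model = tune_top(train, board.best_family, budget, it_seed, folds, feature_columns)
        cm = evaluate(model, test)
        prec = dict(zip((int(c) for c in cm.classes), cm.precision_per_class))
        dropped = min(prec, key=lambda c: (prec[c], c))
        steps.append(
            EliminationStep(
                remaining=list(remaining),
                dropped=dropped,
                family=model.family,
                accuracy=cm.accuracy,
                macro_precision=cm.macro_precision,
                macro_sensitivity=cm.macro_sensitivity,
                per_class_precision=prec,
            )
        )
        remaining = [c for c in remaining if c != dropped]
    return EliminationTrace(steps)


def y_scramble(
    train: pd.DataFrame,
    test: pd.DataFrame,
    family: str,
    repeats: int = 100,
    seed: int = 0,
    feature_columns: list[str] | None = None,
) -> tuple[np.ndarray, float]:
    """Label-permutation control.

    Each repeat permutes the training labels, refits the untuned family and
    scores it on the untouched test set.  Returns the scrambled accuracies
    and the unscrambled reference accuracy; a model free of chance
    correlation collapses to ~1/K under scrambling.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    rng = np.random.default_rng(seed)
    ref_model = fit_family(train, family, _child_seed(rng), feature_columns)
    reference = evaluate(ref_model, test).accuracy
    scores = np.empty(repeats)
    for i in range(repeats):
        shuffled = train.copy()
        shuffled["label"] = rng.permutation(train["label"].to_numpy())
        model = fit_family(shuffled, family, _child_seed(rng), feature_columns)
        pred = model.predict_labels(test)
        scores[i] = float(np.mean(pred == test["label"].to_numpy()))
    return scores, float(reference)


def feature_importance(
    train: pd.DataFrame,
    family: str = "lightgbm",
    seed: int = 0,
    feature_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Gain-weighted split importance from a tree-ensemble family.

    Importance of a feature is the total improvement of the split criterion
    over all splits on it, weighted by the observations each node handles;
    returned sorted descending.
    """
    if family not in TREE_ENSEMBLE_FAMILIES:
        raise ValueError(f"{family!r} is not a tree-ensemble family")
    feature_columns = list(FEATURE_COLUMNS) if feature_columns is None else feature_columns
    model = fit_family(train, family, seed, feature_columns)
    clf = model.classifier
    if family == "lightgbm":
        gains = clf.booster_.feature_importance(importance_type="gain")
    else:
        gains = clf.feature_importances_
    out = pd.DataFrame({"feature": feature_columns, "gain": np.asarray(gains, dtype=float)})
    return out.sort_values("gain", ascending=False, kind="mergesort").reset_index(drop=True)


def feature_ablation_curve(
    train: pd.DataFrame,
    test: pd.DataFrame,
    ranking: list[str],
    family: str,
    seed: int = 0,
) -> pd.DataFrame:
    """Test accuracy vs number of retained features.

    Retrains the untuned family with the top-j features for j from all down
    to 1, discarding features in reverse order of importance.
    """
    missing = [c for c in ranking if c not in train.columns]
    if missing:
        raise ValueError(f"ranking names unknown features: {missing}")
    rows = []
    for j in range(len(ranking), 0, -1):
        feats = list(ranking[:j])
        model = fit_family(train, family, seed, feats)
        rows.append({"n_features": j, "accuracy": evaluate(model, test).accuracy})
    return pd.DataFrame(rows)


def learning_curve(
    table: pd.DataFrame,
    sizes: list[int],
    family: str,
    seed: int = 0,
    test_fraction: float = 0.2,
    feature_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Test accuracy vs observations per class.

    For each size n: subsample n records per class without replacement,
    fresh stratified split, fit the untuned family, evaluate.
    """
    counts = table["label"].value_counts()
    rng = np.random.default_rng(seed)
    rows = []
    for n in sizes:
        too_small = counts[counts < n]
        if len(too_small):
            raise ValueError(
                f"classes with fewer than {n} records: {sorted(too_small.index.tolist())}"
            )
        sub_seed = _child_seed(rng)
        sub = pd.concat(
            [
                g.sample(n=n, random_state=sub_seed)
                for _, g in table.groupby("label")
            ]
        ).reset_index(drop=True)
        train, test = stratified_split(sub, test_fraction, sub_seed)
        model = fit_family(train, family, sub_seed, feature_columns)
        rows.append({"per_class": n, "accuracy": evaluate(model, test).accuracy})
    return pd.DataFrame(rows)


@dataclass
class PcaResult:
    """PCA of the fingerprint table: loadings, top scores, variance shares."""

    components: np.ndarray  # (n_features, n_features) loadings, rows = PCs
    scores: np.ndarray  # (n_samples, n_kept)
    explained_pct: np.ndarray  # all components, sums to 100

    def to_frame(self, n: int | None = None) -> pd.DataFrame:
        n = self.scores.shape[1] if n is None else n
        return pd.DataFrame(
            self.scores[:, :n], columns=[f"PC{i + 1}" for i in range(n)]
        )


def pca_fingerprint(
    table: pd.DataFrame,
    components: int = 3,
    standardize: bool = False,
    feature_columns: list[str] | None = None,
) -> PcaResult:
    """Principal component analysis of the 14-feature fingerprints.

    Features are mean-centered (no variance scaling) and decomposed by SVD,
    as MATLAB's ``pca`` does by default; ``standardize=True`` applies
    Z-scores first.  Scores are returned for the requested top components;
    explained-variance percentages cover all components and sum to 100.
    """
    feature_columns = list(FEATURE_COLUMNS) if feature_columns is None else feature_columns
    if components > len(feature_columns):
        raise ValueError("components exceeds the number of features")
    X = table[feature_columns].to_numpy(dtype=float)
    if standardize:
        sd = X.std(axis=0)
        X = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    pca = PCA(n_components=min(X.shape[0], len(feature_columns)), svd_solver="full")
    scores = pca.fit_transform(X)
    return PcaResult(
        components=pca.components_,
        scores=scores[:, :components],
        explained_pct=pca.explained_variance_ratio_ * 100.0,
    )


@dataclass(frozen=True)
class MixtureSpec:
    """Equal-ratio virtual mixture drawn from a held-out unseen pool."""

    class_ids: tuple[int, ...]
    per_class: int

    def __post_init__(self) -> None:
        if self.per_class < 1:
            raise ValueError("per_class must be >= 1")
        if len(set(self.class_ids)) != len(self.class_ids):
            raise ValueError("class ids must be unique")


def make_mixture(
    spec: MixtureSpec, pool: pd.DataFrame, seed: int = 0
) -> tuple[pd.DataFrame, pd.Series]:
    """Sample an unlabeled equal-ratio mixture plus a sealed scoring key."""
    rng = np.random.default_rng(seed)
    parts = []
    for cid in spec.class_ids:
        cls = pool[pool["label"] == cid]
        if len(cls) < spec.per_class:
            raise ValueError(
                f"pool has only {len(cls)} records of class {cid}, "
                f"need {spec.per_class}"
            )
        take = cls.sample(n=spec.per_class, random_state=_child_seed(rng))
        parts.append(take)
    mixed = pd.concat(parts).sample(frac=1.0, random_state=_child_seed(rng)).reset_index(drop=True)
    key = mixed["label"].copy()
    unlabeled = mixed.drop(columns=["label"])
    return unlabeled, key


def evaluate_mixture(
    model: ReaderModel, table: pd.DataFrame, key: pd.Series
) -> tuple[ConfusionMatrix, pd.Series]:
    """Score mixture predictions against the sealed key."""
    pred, hist = predict(model, table)
    cm = ConfusionMatrix.from_predictions(key.to_numpy(), pred, model.classes)
    return cm, hist
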