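"""Shared fixtures: synthetic blob tables and the two simulated study regimes.

The end-to-end regimes (26 barcode classes, 200 particles per class, full
image simulation + localization) are expensive, so they are built once per
session and shared by the reader, analysis and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from sklearn.datasets import make_blobs

from nanobarcode.localize import FEATURE_COLUMNS, LocalizeParams, build_feature_table
from nanobarcode.reader import compare_models, evaluate, stratified_split, tune_top
from nanobarcode.scheme import enumerate_barcodes
from nanobarcode.simulate import HeterogeneityParams, generate_dataset

#: Study conditions: an easy (tight heterogeneity) and a paper-like hard
#: regime; 200 particles per class in both.
EASY_HET = HeterogeneityParams(radius_cv=0.02, encapsulation_sd=0.05)
HARD_HET = HeterogeneityParams(radius_cv=0.1, encapsulation_sd=1.0)
PARTICLES_PER_CLASS = 200

#: Scaled-down pipeline settings used for the end-to-end experiments.
E2E_ROSTER = ("lightgbm", "lda", "knn")
E2E_COMPARE_FOLDS = 10
E2E_TUNE_FOLDS = 3
E2E_TUNE_BUDGET = 5


def make_blob_table(
    n_classes: int,
    n_per_class: int,
    cluster_std: float = 1.0,
    seed: int = 0,
    center_box: float = 20.0,
) -> pd.DataFrame:
    """A 14-feature Gaussian-blob classification table with labels 1..K."""
    X, y = make_blobs(
        n_samples=n_classes * n_per_class,
        n_features=len(FEATURE_COLUMNS),
        centers=n_classes,
        cluster_std=cluster_std,
        center_box=(-center_box, center_box),
        random_state=seed,
    )
    table = pd.DataFrame(X, columns=FEATURE_COLUMNS)
    table["label"] = y + 1
    return table


def simulate_regime(het: HeterogeneityParams, seed: int) -> pd.DataFrame:
    codes = enumerate_barcodes()
    fovs, truth = generate_dataset(
        codes, particles_per_class=PARTICLES_PER_CLASS, het=het, seed=seed
    )
    table = build_feature_table(fovs, LocalizeParams(), truth)
    return table[table["label"] >= 0].reset_index(drop=True)


def run_reader_pipeline(table: pd.DataFrame, seed: int, feature_columns=None) -> dict:
    """Stratified split -> roster comparison -> tune top -> held-out eval."""
    train, test = stratified_split(table, 0.2, seed)
    board = compare_models(
        train, E2E_ROSTER, E2E_COMPARE_FOLDS, seed, feature_columns
    )
    model = tune_top(
        train, board.best_family, E2E_TUNE_BUDGET, seed, E2E_TUNE_FOLDS, feature_columns
    )
    cm = evaluate(model, test)
    return {
        "train": train,
        "test": test,
        "leaderboard": board,
        "model": model,
        "confusion": cm,
        "accuracy": cm.accuracy,
    }


@pytest.fixture(scope="session")
def easy_table() -> pd.DataFrame:
    return simulate_regime(EASY_HET, seed=11)


@pytest.fixture(scope="session")
def hard_table() -> pd.DataFrame:
    return simulate_regime(HARD_HET, seed=12)


@pytest.fixture(scope="session")
def easy_eval(easy_table) -> dict:
    return run_reader_pipeline(easy_table, seed=7)


@pytest.fixture(scope="session")
def hard_eval(hard_table) -> dict:
    return run_reader_pipeline(hard_table, seed=7)
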