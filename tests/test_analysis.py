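"""Analysis suite: elimination, scrambling, importance, PCA, mixtures."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_blob_table
from nanobarcode.analysis import (
    MixtureSpec,
    backward_eliminate,
    evaluate_mixture,
    feature_ablation_curve,
    feature_importance,
    learning_curve,
    make_mixture,
    pca_fingerprint,
    y_scramble,
)
from nanobarcode.localize import FEATURE_COLUMNS
from nanobarcode.reader import evaluate, fit_family, stratified_split


class TestBackwardElimination:
    def test_separable_classes_stay_perfect(self):
        table = make_blob_table(3, 60, cluster_std=1.0, seed=1)
        trace = backward_eliminate(table, ("lda",), seed=2, folds=3, budget=1)
        df = trace.to_frame()
        assert len(df) == 3
        assert np.all(df["accuracy"].to_numpy() == 1.0)

    def test_structure_ten_classes(self):
        """A 10-class table yields 10 iterations ending at a single class,
        each dropping the argmin-precision class of its own evaluation."""
        table = make_blob_table(10, 30, cluster_std=6.0, seed=3)
        trace = backward_eliminate(table, ("lda",), seed=4, folds=3, budget=1)
        assert len(trace.steps) == 10
        assert [len(s.remaining) for s in trace.steps] == list(range(10, 0, -1))
        assert len(trace.steps[-1].remaining) == 1
        for step in trace.steps[:-1]:
            prec = step.per_class_precision
            expected = min(prec, key=lambda c: (prec[c], c))
            assert step.dropped == expected
            assert step.dropped in step.remaining
        # each iteration removes exactly the dropped class
        for a, b in zip(trace.steps, trace.steps[1:]):
            assert set(b.remaining) == set(a.remaining) - {a.dropped}

    def test_single_class_rejected(self):
        table = make_blob_table(1, 30, seed=5)
        with pytest.raises(ValueError):
            backward_eliminate(table, ("lda",))


class TestYScrambling:
    def test_scrambled_accuracy_collapses_to_chance(self):
        """Balanced K classes: mean scrambled accuracy lands within 3 points
        of 100/K %.  Overlapping classes are used so the null model's test
        predictions are effectively independent draws."""
        table = make_blob_table(5, 120, cluster_std=30.0, seed=6)
        train, test = stratified_split(table, 0.25, seed=7)
        scores, _ = y_scramble(train, test, "lda", repeats=10, seed=8)
        assert len(scores) == 10
        assert abs(scores.mean() - 0.2) < 0.03

    def test_signal_beats_chance_on_separable_data(self):
        table = make_blob_table(5, 120, cluster_std=1.0, seed=6)
        train, test = stratified_split(table, 0.25, seed=7)
        scores, reference = y_scramble(train, test, "lda", repeats=10, seed=8)
        assert reference > scores.max()

    def test_single_repeat(self):
        table = make_blob_table(3, 40, cluster_std=1.0, seed=9)
        train, test = stratified_split(table, 0.2, seed=10)
        scores, _ = y_scramble(train, test, "naive_bayes", repeats=1, seed=11)
        assert scores.shape == (1,)

    def test_distribution_tightens_with_test_size(self):
        """The scrambled-accuracy sd shrinks as the test set grows."""
        sds = []
        for n_per_class in (40, 400):
            table = make_blob_table(4, n_per_class, cluster_std=30.0, seed=12)
            train, test = stratified_split(table, 0.5, seed=13)
            scores, _ = y_scramble(train, test, "naive_bayes", repeats=8, seed=14)
            sds.append(scores.std())
        assert sds[1] < sds[0]


class TestFeatureImportance:
    def test_informative_feature_ranked_first(self):
        """One label-carrying feature vs thirteen pure-noise features."""
        rng = np.random.default_rng(15)
        n = 600
        y = rng.integers(1, 4, size=n)
        X = rng.normal(size=(n, len(FEATURE_COLUMNS)))
        X[:, 5] = y * 2.0 + rng.normal(0, 0.3, size=n)  # informative: I_zeta
        table = pd.DataFrame(X, columns=FEATURE_COLUMNS)
        table["label"] = y
        ranking = feature_importance(table, "lightgbm", seed=16)
        assert ranking.iloc[0]["feature"] == "I_zeta"
        assert len(ranking) == len(FEATURE_COLUMNS)
        assert np.all(ranking["gain"].to_numpy() >= 0)

    def test_non_tree_family_rejected(self):
        table = make_blob_table(2, 30, seed=17)
        with pytest.raises(ValueError):
            feature_importance(table, "lda")


class TestAblationCurve:
    def test_full_feature_set_reproduces_baseline(self):
        table = make_blob_table(4, 60, cluster_std=4.0, seed=18)
        train, test = stratified_split(table, 0.25, seed=19)
        ranking = list(FEATURE_COLUMNS)
        curve = feature_ablation_curve(train, test, ranking, "decision_tree", seed=20)
        assert len(curve) == 14
        baseline = evaluate(fit_family(train, "decision_tree", 20), test).accuracy
        assert curve[curve.n_features == 14]["accuracy"].iloc[0] == baseline

    def test_unknown_feature_rejected(self):
        table = make_blob_table(2, 30, seed=21)
        train, test = stratified_split(table, 0.2, seed=22)
        with pytest.raises(ValueError):
            feature_ablation_curve(train, test, ["bogus"], "decision_tree")


class TestLearningCurve:
    def test_more_observations_help_on_hard_data(self, hard_table):
        curve = learning_curve(hard_table, [30, 120], "lightgbm", seed=23)
        acc = dict(zip(curve["per_class"], curve["accuracy"]))
        assert acc[120] >= acc[30]

    def test_single_size_and_oversize_error(self):
        table = make_blob_table(3, 50, cluster_std=1.0, seed=24)
        curve = learning_curve(table, [40], "lda", seed=25)
        assert len(curve) == 1
        with pytest.raises(ValueError):
            learning_curve(table, [60], "lda", seed=26)


class TestPca:
    def test_line_in_14d_loads_on_single_component(self):
        t = np.linspace(0, 1, 80)
        direction = np.arange(1, 15, dtype=float)
        X = np.outer(t, direction)
        table = pd.DataFrame(X, columns=FEATURE_COLUMNS)
        res = pca_fingerprint(table, components=2)
        assert res.explained_pct[0] == pytest.approx(100.0, abs=1e-8)

    def test_variance_sums_to_100(self):
        table = make_blob_table(4, 50, cluster_std=2.0, seed=27)
        res = pca_fingerprint(table, components=3)
        assert res.explained_pct.sum() == pytest.approx(100.0)
        assert np.all(np.diff(res.explained_pct) <= 1e-9)
        # scores of distinct components are uncorrelated
        cov = np.cov(res.scores.T)
        off = cov - np.diag(np.diag(cov))
        assert np.all(np.abs(off) < 1e-8 * max(1.0, np.abs(cov).max()))

    def test_matches_eigendecomposition_oracle(self):
        """Explained variances match an independent eigendecomposition of
        the centered covariance matrix on a small instance."""
        rng = np.random.default_rng(28)
        X = rng.normal(size=(40, 14)) @ rng.normal(size=(14, 14))
        table = pd.DataFrame(X, columns=FEATURE_COLUMNS)
        res = pca_fingerprint(table, components=3)
        C = np.cov((X - X.mean(axis=0)).T)
        eig = np.sort(np.linalg.eigvalsh(C))[::-1]
        assert res.explained_pct == pytest.approx(100 * eig / eig.sum(), rel=1e-8)

    def test_centering_invariance(self):
        """Scores are invariant to feature-wise mean shifts."""
        table = make_blob_table(3, 40, cluster_std=1.0, seed=29)
        shifted = table.copy()
        shifted[FEATURE_COLUMNS] = shifted[FEATURE_COLUMNS] + np.arange(14) * 100.0
        a = pca_fingerprint(table, components=3)
        b = pca_fingerprint(shifted, components=3)
        assert np.allclose(np.abs(a.scores), np.abs(b.scores), atol=1e-6)

    def test_too_many_components_rejected(self):
        table = make_blob_table(2, 30, seed=30)
        with pytest.raises(ValueError):
            pca_fingerprint(table, components=15)


class TestMixtures:
    def test_mixture_shape_and_blinding(self):
        pool = make_blob_table(4, 150, cluster_std=1.0, seed=31)
        spec = MixtureSpec(class_ids=(1, 3), per_class=100)
        unlabeled, key = make_mixture(spec, pool, seed=32)
        assert len(unlabeled) == 200
        assert "label" not in unlabeled.columns
        assert sorted(key.value_counts().to_dict().items()) == [(1, 100), (3, 100)]

    def test_separable_mixture_scores_perfectly(self):
        pool = make_blob_table(3, 100, cluster_std=1.0, seed=33)
        train, test = stratified_split(pool, 0.3, seed=34)
        model = fit_family(train, "lda", 0)
        unlabeled, key = make_mixture(MixtureSpec((1, 2, 3), 20), test, seed=35)
        cm, hist = evaluate_mixture(model, unlabeled, key)
        assert cm.accuracy == 1.0
        assert hist.sum() == 60

    def test_insufficient_pool_rejected(self):
        pool = make_blob_table(2, 10, seed=36)
        with pytest.raises(ValueError):
            make_mixture(MixtureSpec((1,), 50), pool, seed=37)

    def test_full_roster_mixture_reproduces_test_precisions(self):
        """Scoring a mixture over all classes mirrors the per-class
        precisions of the standard held-out evaluation."""
        pool = make_blob_table(5, 200, cluster_std=6.0, seed=38)
        train, test = stratified_split(pool, 0.4, seed=39)
        model = fit_family(train, "lda", 0)
        cm_test = evaluate(model, test)
        unlabeled, key = make_mixture(MixtureSpec((1, 2, 3, 4, 5), 70), test, seed=40)
        cm_mix, _ = evaluate_mixture(model, unlabeled, key)
        assert np.all(
            np.abs(cm_mix.precision_per_class - cm_test.precision_per_class) < 0.15
        )
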