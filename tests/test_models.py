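"""Model protocol: splits, CV grid search, metrics, importances."""

import numpy as np
import pytest

from imfold import (
    BalancedRandomForestClassifier,
    FoldingClassifier,
    StrengthRegressor,
    cv_grid_search,
    feature_importance,
    load_results,
    split_dataset,
)
from imfold.models import _classification_metrics, _regression_metrics
from imfold.synthetic import (
    SyntheticSpec,
    gen_classification_features,
    gen_strength_table,
)
from imfold.datasets import build_regression_dataset


@pytest.fixture(scope="module")
def strength_data():
    """Featurised synthetic strength table at n=500, sigma=0.05."""
    table = gen_strength_table(500, SyntheticSpec(seed=42))
    X, y, _ = build_regression_dataset(table)
    return X.to_numpy(), y


@pytest.fixture(scope="module")
def imbalanced_data():
    """99:1 synthetic imbalance with informative motif features."""
    X, y = gen_classification_features(n_minority=8, imbalance=99, seed=7)
    return X.to_numpy(), y


class TestSplitDataset:
    def test_90_10_shape(self):
        X = np.random.default_rng(0).normal(size=(100, 3))
        y = np.r_[np.ones(50), np.zeros(50)].astype(int)
        X_tr, X_te, y_tr, y_te = split_dataset(X, y, 0.1, seed=1)
        assert len(X_tr) == 90 and len(X_te) == 10

    def test_80_20_gives_24_of_120(self):
        """The regression protocol: 20% of 120 rows is a 24-row test set."""
        X = np.random.default_rng(0).normal(size=(120, 5))
        y = np.random.default_rng(1).normal(size=120)
        X_tr, X_te, _, _ = split_dataset(X, y, 0.2, seed=0, stratify=False)
        assert len(X_tr) == 96 and len(X_te) == 24

    def test_reproducible_and_disjoint(self):
        X = np.arange(200).reshape(100, 2)
        y = np.r_[np.ones(50), np.zeros(50)].astype(int)
        a = split_dataset(X, y, 0.1, seed=3)
        b = split_dataset(X, y, 0.1, seed=3)
        np.testing.assert_array_equal(a[1], b[1])
        rows = {tuple(r) for r in a[0]} | {tuple(r) for r in a[1]}
        assert len(rows) == 100

    def test_stratified_ratio_preserved(self):
        y = np.r_[np.ones(10), np.zeros(90)].astype(int)
        X = np.arange(100).reshape(-1, 1)
        for seed in range(5):
            _, _, y_tr, y_te = split_dataset(X, y, 0.1, seed=seed)
            assert y_te.sum() == 1 and y_tr.sum() == 9

    def test_bad_fraction(self):
        with pytest.raises(ValueError):
            split_dataset(np.zeros((10, 1)), np.zeros(10), 1.5, seed=0)


class TestMetrics:
    def test_confusion_matrix_arithmetic(self):
        """TP=77 FN=23 TN=81 FP=19 -> recall .77, specificity .81, acc .79."""
        y_true = np.r_[np.ones(100), np.zeros(100)].astype(int)
        y_pred = np.r_[np.ones(77), np.zeros(23), np.zeros(81), np.ones(19)].astype(int)
        m = _classification_metrics(y_true, y_pred, y_pred.astype(float))
        assert m["recall"] == pytest.approx(0.77)
        assert m["specificity"] == pytest.approx(0.81)
        assert m["accuracy"] == pytest.approx(0.79)
        assert m["balanced_accuracy"] == pytest.approx((0.77 + 0.81) / 2)

    def test_balanced_accuracy_identity(self, rng):
        for _ in range(10):
            y = rng.integers(0, 2, size=60)
            p = rng.integers(0, 2, size=60)
            if len(np.unique(y)) < 2:
                continue
            m = _classification_metrics(y, p, rng.random(60))
            assert m["balanced_accuracy"] == pytest.approx(
                (m["recall"] + m["specificity"]) / 2, abs=1e-12
            )

    def test_auroc_extremes(self, rng):
        y = rng.integers(0, 2, size=400)
        m = _classification_metrics(y, y, y.astype(float))
        assert m["auroc"] == 1.0
        rand_aucs = [
            _classification_metrics(y, y, np.random.default_rng(s).random(400))["auroc"]
            for s in range(10)
        ]
        assert abs(np.mean(rand_aucs) - 0.5) < 0.05

    def test_auroc_missing_single_class(self):
        m = _classification_metrics(np.ones(5, int), np.ones(5, int), np.ones(5))
        assert np.isnan(m["auroc"])

    def test_regression_extremes(self, rng):
        y = rng.normal(size=50)
        perfect = _regression_metrics(y, y)
        assert perfect["r2"] == 1 and perfect["rmse"] == 0 and perfect["mae"] == 0
        mean_pred = _regression_metrics(y, np.full(50, y.mean()))
        assert mean_pred["r2"] == pytest.approx(0, abs=1e-12)

    def test_rmse_dominates_mae(self, rng):
        y, p = rng.normal(size=50), rng.normal(size=50)
        m = _regression_metrics(y, p)
        assert m["rmse"] >= m["mae"] >= 0


class TestBalancedForest:
    def test_imbalanced_superiority(self, imbalanced_data):
        """On ~99:1 data the balanced forest beats the majority baseline by
        a wide balanced-accuracy margin and the plain forest on recall."""
        X, y = imbalanced_data
        X_tr, X_te, y_tr, y_te = split_dataset(X, y, 0.25, seed=0)
        grid = {"n_estimators": [100]}
        bal = FoldingClassifier(X_tr, y_tr, "balanced_rf", grid, seed=0).fit(folds=3)
        plain = FoldingClassifier(X_tr, y_tr, "rf", grid, seed=0).fit(folds=3)
        mb = bal.evaluate(X_te, y_te)
        mp = plain.evaluate(X_te, y_te)
        assert mb["balanced_accuracy"] >= 0.8  # >= 0.5 + 0.3
        assert mb["recall"] >= mp["recall"]

    def test_binary_only(self):
        with pytest.raises(ValueError, match="binary"):
            BalancedRandomForestClassifier(n_estimators=5, random_state=0).fit(
                np.zeros((6, 2)), np.array([0, 0, 1, 1, 2, 2])
            )

    def test_deterministic_given_seed(self, imbalanced_data):
        X, y = imbalanced_data
        a = BalancedRandomForestClassifier(n_estimators=20, random_state=5).fit(X, y)
        b = BalancedRandomForestClassifier(n_estimators=20, random_state=5).fit(X, y)
        np.testing.assert_array_equal(a.predict_proba(X), b.predict_proba(X))


class TestCVGridSearch:
    def test_single_point_grid_passthrough(self, strength_data):
        X, y = strength_data
        make = lambda p, s: __import__("sklearn.ensemble", fromlist=["x"]).GradientBoostingRegressor(
            random_state=s, **p
        )
        best, table = cv_grid_search(
            make, {"n_estimators": [50]}, X, y, folds=3,
            scoring="r2", classification=False,
        )
        assert best == {"n_estimators": 50}
        assert set(table["fold"]) == {0, 1, 2}

    def test_separable_classification_auroc(self):
        X, y = gen_classification_features(n_minority=15, imbalance=10, seed=1)
        best, table = cv_grid_search(
            lambda p, s: BalancedRandomForestClassifier(random_state=s, **p),
            {"n_estimators": [50]}, X.to_numpy(), y, folds=5, scoring="auroc",
        )
        assert table.groupby("params_id")["auroc"].mean().max() >= 0.95

    def test_noise_free_regression_cv(self):
        spec = SyntheticSpec(seed=9)
        spec = SyntheticSpec(seed=9, strength=spec.strength.__class__(sigma=0.0))
        table = gen_strength_table(300, spec)
        X, y, _ = build_regression_dataset(table)
        res = StrengthRegressor(X.to_numpy(), y, {"n_estimators": [300]}, seed=0).fit()
        assert res.cv_table.groupby("params_id")["r2"].mean().max() >= 0.9

    def test_empty_grid_rejected(self, strength_data):
        X, y = strength_data
        with pytest.raises(ValueError):
            cv_grid_search(lambda p, s: None, {}, X, y)


class TestResultsObjects:
    def test_regressor_parameter_recovery(self, strength_data):
        """Boosted trees recover the synthetic strength map: R2 >= 0.8."""
        X, y = strength_data
        X_tr, X_te, y_tr, y_te = split_dataset(X, y, 0.2, seed=0, stratify=False)
        res = StrengthRegressor(
            X_tr, y_tr, {"n_estimators": [300], "max_depth": [4]}, seed=0
        ).fit(folds=3)
        rep = res.evaluate(X_te, y_te)
        assert rep["r2"] >= 0.8
        assert rep["rmse"] >= rep["mae"] >= 0
        assert "regression" in rep.summary()

    def test_save_load_roundtrip(self, strength_data, tmp_path):
        X, y = strength_data
        res = StrengthRegressor(X, y, {"n_estimators": [50]}, seed=1).fit(folds=2)
        path = tmp_path / "model.joblib"
        res.save(path)
        loaded = load_results(path)
        np.testing.assert_array_equal(loaded.predict(X[:20]), res.predict(X[:20]))
        assert loaded.best_params == res.best_params

    def test_schema_mismatch_rejected(self, strength_data):
        X, y = strength_data
        res = StrengthRegressor(X, y, {"n_estimators": [20]}, seed=1).fit(folds=2)
        with pytest.raises(ValueError, match="feature-count"):
            res.predict(X[:, :10])

    def test_refit_determinism(self, strength_data):
        X, y = strength_data
        a = StrengthRegressor(X, y, {"n_estimators": [50]}, seed=4).fit(folds=2)
        b = StrengthRegressor(X, y, {"n_estimators": [50]}, seed=4).fit(folds=2)
        np.testing.assert_array_equal(a.predict(X[:30]), b.predict(X[:30]))

    def test_single_class_training_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            FoldingClassifier(np.zeros((10, 3)), np.zeros(10, int))

    def test_classifier_summary_mentions_params(self, imbalanced_data):
        X, y = imbalanced_data
        res = FoldingClassifier(X, y, grid={"n_estimators": [30]}, seed=0).fit(folds=2)
        assert "n_estimators" in res.summary()


class TestFeatureImportance:
    def test_sign_recovery(self, strength_data):
        """Stabilising loop C/T densities land in the positive-PCC group,
        destabilising loop G/A densities in the negative group."""
        X, y = strength_data
        res = StrengthRegressor(
            X, y, {"n_estimators": [300], "max_depth": [4]}, seed=0
        ).fit(folds=2)
        table = feature_importance(res, X, y)
        sign = dict(zip(table["feature"], table["sign"]))
        assert sign["C_density_loops"] == "positive"
        assert sign["T_density_loops"] == "positive"
        assert sign["G_density_loops"] == "negative"
        assert sign["A_density_loops"] == "negative"
        assert sign["c_tract_length"] == "positive"
        assert sign["loop_length"] == "negative"

    def test_importances_nonnegative_and_ranked(self, strength_data):
        X, y = strength_data
        res = StrengthRegressor(X, y, {"n_estimators": [100]}, seed=0).fit(folds=2)
        table = feature_importance(res, X, y)
        assert (table["importance"] >= 0).all()
        assert 0 < table["importance"].sum() < np.inf
        assert table["importance"].is_monotonic_decreasing
        assert table[table["top_group"]].groupby("sign").size().max() <= 10

    def test_constant_feature_zero_importance(self, strength_data):
        X, y = strength_data
        X2 = np.c_[X[:, :32], np.zeros(len(X))]
        res = StrengthRegressor(X2, y, {"n_estimators": [50]}, seed=0).fit(folds=2)
        table = feature_importance(res, X2, y)
        last = table[table["feature"] == res.feature_names[32]]
        assert float(last["importance"].iloc[0]) == 0.0

    def test_requires_tree_model(self, strength_data):
        X, y = strength_data
        res = StrengthRegressor(X, y, {"n_estimators": [20]}, seed=0).fit(folds=2)
        res.model = object()
        with pytest.raises(TypeError):
            feature_importance(res, X, y)
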