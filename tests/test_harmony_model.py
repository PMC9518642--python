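import json

import numpy as np
import pandas as pd
import pytest

from chromaharmony import harmony_model as hm
from chromaharmony import synthetic


@pytest.fixture
def ref():
    return hm.reference_model()


@pytest.fixture
def simple_norm():
    return hm.NormParams(minimum={"f1": 10.0, "f2": 0.0}, maximum={"f1": 30.0, "f2": 0.0})


class TestNormParams:
    def test_min_maps_to_zero_max_to_one(self, simple_norm):
        out = simple_norm.transform(pd.DataFrame({"f1": [10.0, 30.0]}))
        np.testing.assert_allclose(out["f1"], [0.0, 1.0])

    def test_midpoint(self, simple_norm):
        out = simple_norm.transform(pd.DataFrame({"f1": [20.0]}))
        assert out["f1"].iloc[0] == pytest.approx(0.5)

    def test_fit_then_transform_in_unit_interval(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame(rng.normal(size=(50, 3)) * 10, columns=["a", "b", "c"])
        norm = hm.NormParams.fit(table)
        out = norm.transform(table)
        assert (out.to_numpy() >= 0).all() and (out.to_numpy() <= 1).all()

    def test_out_of_range_clamped_with_warning(self, simple_norm, caplog):
        with caplog.at_level("WARNING"):
            out = simple_norm.transform(pd.DataFrame({"f1": [50.0, -5.0]}))
        np.testing.assert_allclose(out["f1"], [1.0, 0.0])
        assert any("clamped" in r.message for r in caplog.records)

    def test_constant_feature_maps_to_zero(self, simple_norm):
        out = simple_norm.transform(pd.DataFrame({"f2": [0.0, 0.0]}))
        np.testing.assert_array_equal(out["f2"], [0.0, 0.0])

    def test_unfitted_norm_rejected(self):
        with pytest.raises(ValueError, match="unfitted"):
            hm.normalize(pd.DataFrame({"f1": [1.0]}), None)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError, match="max < min"):
            hm.NormParams(minimum={"f1": 2.0}, maximum={"f1": 1.0})


class TestPredictHarmony:
    def test_all_zero_features_returns_intercept(self, ref):
        score = hm.predict_harmony(ref, {n: 0.0 for n in ref.feature_names})
        assert score == 0.249

    def test_unit_f1_increment(self, ref):
        x = {n: 0.0 for n in ref.feature_names}
        x["f1"] = 1.0
        assert hm.predict_harmony(ref, x) == pytest.approx(0.249 + 1.499, abs=1e-12)

    def test_zero_coefficient_model_is_constant(self):
        model = hm.HarmonyModel(intercept=0.7, coefficients={"f1": 0.0, "f2": 0.0})
        rng = np.random.default_rng(0)
        for _ in range(5):
            assert model.predict({"f1": rng.random(), "f2": rng.random()}) == 0.7

    def test_missing_feature_rejected_by_name(self, ref):
        with pytest.raises(KeyError, match="f14"):
            hm.predict_harmony(ref, {n: 0.0 for n in ref.feature_names if n != "f14"})

    def test_affine_in_features(self, ref):
        rng = np.random.default_rng(1)
        a = pd.DataFrame(rng.random((1, 7)), columns=ref.feature_names)
        b = pd.DataFrame(rng.random((1, 7)), columns=ref.feature_names)
        lam = 0.3
        mix = lam * a + (1 - lam) * b
        assert hm.predict_harmony(ref, mix)[0] == pytest.approx(
            lam * hm.predict_harmony(ref, a)[0] + (1 - lam) * hm.predict_harmony(ref, b)[0]
        )

    def test_reference_model_constants(self, ref):
        assert ref.intercept == 0.249
        assert ref.coefficients == {
            "f1": 1.499,
            "f4": 0.408,
            "f5": -0.594,
            "f11": -0.52,
            "f13": -0.47,
            "f14": -1.386,
            "f15": 0.862,
        }


class TestPadToHarmony:
    def test_neutral_point(self):
        assert hm.pad_to_harmony(0.0, 0.0) == 0.374

    def test_unit_pleasure(self):
        assert hm.pad_to_harmony(1.0, 0.0) == pytest.approx(1.187, abs=1e-12)

    def test_linearity(self):
        p, a = 0.7, -0.4
        assert hm.pad_to_harmony(2 * p, 2 * a) - 0.374 == pytest.approx(
            2 * (hm.pad_to_harmony(p, a) - 0.374), abs=1e-12
        )

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError, match="finite"):
            hm.pad_to_harmony(float("nan"), 0.0)


class TestFitOls:
    def test_noiseless_recovery_exact(self, ref):
        X, y = synthetic.make_feature_dataset(200, ref, noise_sd=0.0, seed=0)
        fitted = hm.fit_ols(X, y)
        assert fitted.intercept == pytest.approx(ref.intercept, abs=1e-8)
        for name, coef in ref.coefficients.items():
            assert fitted.coefficients[name] == pytest.approx(coef, abs=1e-8)

    def test_noisy_recovery_within_three_standard_errors(self, ref):
        X, y = synthetic.make_feature_dataset(500, ref, noise_sd=0.1, seed=1)
        fitted = hm.fit_ols(X, y)
        design = np.column_stack([np.ones(len(X)), X.to_numpy()])
        pred = np.atleast_1d(hm.predict_harmony(fitted, X))
        dof = len(y) - design.shape[1]
        sigma2 = float(((y - pred) ** 2).sum()) / dof
        cov = sigma2 * np.linalg.inv(design.T @ design)
        se = np.sqrt(np.diag(cov))
        assert abs(fitted.intercept - ref.intercept) <= 3 * se[0]
        for i, name in enumerate(ref.feature_names):
            assert abs(fitted.coefficients[name] - ref.coefficients[name]) <= 3 * se[i + 1]

    def test_constant_target(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.random((40, 3)), columns=["a", "b", "c"])
        fitted = hm.fit_ols(X, np.full(40, 1.7))
        assert fitted.intercept == pytest.approx(1.7, abs=1e-9)
        for coef in fitted.coefficients.values():
            assert coef == pytest.approx(0.0, abs=1e-9)

    def test_residuals_orthogonal_to_columns(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.random((60, 4)), columns=list("abcd"))
        y = rng.normal(size=60)
        fitted = hm.fit_ols(X, y)
        resid = y - np.atleast_1d(hm.predict_harmony(fitted, X))
        for col in X.columns:
            assert abs(float(X[col] @ resid)) <= 1e-8

    def test_rank_deficient_rejected_without_fallback(self):
        X = pd.DataFrame({"a": np.arange(20.0), "b": 2 * np.arange(20.0)})
        with pytest.raises(ValueError, match="rank deficient"):
            hm.fit_ols(X, np.arange(20.0))
        fitted = hm.fit_ols(X, np.arange(20.0), ridge_fallback=True)
        assert np.isfinite(list(fitted.coefficients.values())).all()

    def test_backward_elimination_drops_pure_noise_feature(self, ref):
        rng = np.random.default_rng(4)
        X, y = synthetic.make_feature_dataset(300, ref, noise_sd=0.05, seed=4)
        X["junk"] = rng.random(300)
        fitted = hm.fit_ols(X, y, eliminate=True, cv_k=5, seed=0)
        assert "f1" in fitted.coefficients  # strong feature survives
        assert len(fitted.feature_names) <= 8


class TestClassify:
    @pytest.mark.parametrize("score,expected", [(0.249, True), (-0.1, False), (0.0, False)])
    def test_threshold_semantics(self, score, expected):
        model = hm.HarmonyModel(intercept=score, coefficients={"f1": 0.0})
        assert hm.classify(model, {"f1": 0.0}) is expected

    def test_true_model_classifies_noiseless_labels_perfectly(self, ref):
        X, y = synthetic.make_feature_dataset(200, ref, noise_sd=0.0, seed=5)
        pred = hm.classify(ref, X)
        assert hm.correct_classification_rate(pred, y > 0) == 1.0


class TestMetrics:
    def test_perfect(self):
        assert hm.mae([1, 2], [1, 2]) == 0.0
        assert hm.rmse([1, 2], [1, 2]) == 0.0

    def test_symmetric_unit_errors(self):
        assert hm.mae([1, -1], [0, 0]) == 1.0
        assert hm.rmse([1, -1], [0, 0]) == 1.0

    def test_mae_le_rmse(self):
        assert hm.mae([0, 2], [0, 0]) == 1.0
        assert hm.rmse([0, 2], [0, 0]) == pytest.approx(np.sqrt(2.0))
        rng = np.random.default_rng(0)
        for _ in range(20):
            p, t = rng.normal(size=10), rng.normal(size=10)
            assert hm.mae(p, t) <= hm.rmse(p, t) + 1e-12

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            hm.mae([1, 2], [1])
        with pytest.raises(ValueError):
            hm.rmse([1, 2], [1])

    def test_cc(self):
        assert hm.correct_classification_rate([1, 0, 1], [1, 0, 1]) == 1.0
        assert hm.correct_classification_rate([0, 1, 0], [1, 0, 1]) == 0.0
        pred = [1, 1, 1, 0, 0, 0, 0, 1]
        truth = [1, 1, 1, 1, 0, 0, 1, 0]  # TP=3, TN=2 of 8
        assert hm.correct_classification_rate(pred, truth) == pytest.approx(0.625)


class TestPearson:
    def test_identity(self):
        x = np.arange(10.0)
        r, p = hm.pearson_r(x, x)
        assert r == pytest.approx(1.0)

    def test_negative_affine(self):
        x = np.arange(10.0)
        r, _ = hm.pearson_r(x, -2 * x + 5)
        assert r == pytest.approx(-1.0)

    def test_null_distribution_at_n164(self):
        rng = np.random.default_rng(0)
        rs = []
        exceed = 0
        for _ in range(100):
            x, y = rng.normal(size=164), rng.normal(size=164)
            r, _ = hm.pearson_r(x, y)
            rs.append(abs(r))
            exceed += abs(r) > 0.2
        assert np.mean(rs) < 0.12
        assert exceed < 5

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            hm.pearson_r(np.ones(10), np.arange(10.0))


class TestKfoldCv:
    def test_noiseless_linear_targets(self, ref):
        X, y = synthetic.make_feature_dataset(100, ref, noise_sd=0.0, seed=6)
        report = hm.kfold_cv(X, y, k=10, seed=0)
        assert report.pearson_r == pytest.approx(1.0, abs=1e-9)
        assert report.mae == pytest.approx(0.0, abs=1e-9)
        assert report.rmse == pytest.approx(0.0, abs=1e-9)
        assert len(report.folds) == 10

    def test_permuted_targets_have_no_signal(self, ref):
        rs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X, y = synthetic.make_feature_dataset(500, ref, noise_sd=0.0, seed=seed)
            report = hm.kfold_cv(X, rng.permutation(y), k=10, seed=seed)
            rs.append(abs(report.pearson_r))
        assert max(rs) < 0.15

    def test_same_seed_identical_report(self, ref):
        X, y = synthetic.make_feature_dataset(80, ref, noise_sd=0.2, seed=7)
        a = hm.kfold_cv(X, y, k=5, seed=3)
        b = hm.kfold_cv(X, y, k=5, seed=3)
        assert a == b

    def test_classification_task(self, ref):
        X, y = synthetic.make_feature_dataset(200, ref, noise_sd=0.0, seed=8)
        report = hm.kfold_cv(X, y, k=10, seed=0, task="classification")
        assert report.cc == pytest.approx(1.0)

    def test_k_exceeding_n_rejected(self, ref):
        X, y = synthetic.make_feature_dataset(10, ref, noise_sd=0.0, seed=9)
        with pytest.raises(ValueError, match="exceeds"):
            hm.kfold_cv(X, y, k=11)


class TestCronbachAlpha:
    def test_identical_raters_give_one(self):
        truth = np.array([-2, -1, 0, 1, 2, 1, 0, -1], dtype=float)
        ratings = np.tile(truth[:, None], (1, 10))
        assert hm.cronbach_alpha(ratings) == pytest.approx(1.0, abs=1e-12)

    def test_independent_noise_raters_near_zero(self):
        rng = np.random.default_rng(0)
        alphas = [
            hm.cronbach_alpha(rng.integers(-2, 3, size=(164, 84)).astype(float))
            for _ in range(20)
        ]
        assert abs(np.mean(alphas)) < 0.1

    def test_alpha_increases_as_noise_decreases(self):
        truth = np.linspace(-2, 2, 50)
        alphas = []
        for sd in (2.0, 1.0, 0.5, 0.25):
            ratings = synthetic.make_rating_matrix(50, 30, truth, noise_sd=sd, seed=1)
            alphas.append(hm.cronbach_alpha(ratings))
        assert all(b > a for a, b in zip(alphas, alphas[1:]))

    def test_invariant_under_rater_constant_shift(self):
        rng = np.random.default_rng(3)
        ratings = rng.normal(size=(30, 6))
        shifted = ratings.copy()
        shifted[:, 2] += 5.0
        assert hm.cronbach_alpha(shifted) == pytest.approx(hm.cronbach_alpha(ratings))

    def test_orientation_transpose(self):
        rng = np.random.default_rng(4)
        ratings = rng.normal(size=(30, 6))
        assert hm.cronbach_alpha(ratings.T, raters="rows") == pytest.approx(
            hm.cronbach_alpha(ratings)
        )

    def test_too_few_raters_rejected(self):
        with pytest.raises(ValueError, match="raters"):
            hm.cronbach_alpha(np.zeros((10, 1)))

    def test_rating_matrix_validation(self):
        good = pd.DataFrame([[1, -2], [0, 2]])
        hm.validate_rating_matrix(good)
        with pytest.raises(ValueError, match="5-level"):
            hm.validate_rating_matrix(pd.DataFrame([[3, 0], [0, 0]]))


class TestModelPersistence:
    def test_json_round_trip(self, tmp_path, ref):
        norm = hm.NormParams(
            minimum={n: 0.0 for n in ref.feature_names},
            maximum={n: 1.0 for n in ref.feature_names},
        )
        model = hm.HarmonyModel(ref.intercept, dict(ref.coefficients), norm=norm, threshold=0.1)
        path = tmp_path / "model.json"
        model.save(path)
        loaded = hm.HarmonyModel.load(path)
        assert loaded == model
        # file is plain JSON with the documented fields
        raw = json.loads(path.read_text())
        assert set(raw) == {"intercept", "coefficients", "norm", "threshold"}

    def test_eval_report_invariant(self):
        with pytest.raises(ValueError, match="MAE"):
            hm.EvalReport(task="regression", mae=2.0, rmse=1.0)
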