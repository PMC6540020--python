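"""Feature construction, linear regression and the feed-forward networks."""

import json
from dataclasses import replace

import numpy as np
import pytest

from wristbia import (
    FEATURE_SETS,
    H2RVariant,
    LinearModel,
    MLPSpec,
    TrainedModel,
    build_feature_matrix,
    build_features,
    estimate_h2r,
    fit_h2r_model,
    fit_ols,
    predict_linear,
    predict_mlp,
    predict_mlp_ensemble,
    train_mlp,
    train_mlp_cv_ensemble,
)
from wristbia.errors import SchemaError, SingularDesignError
from wristbia.models import _fit_network  # white-box: standardization identity
from wristbia.simulate import SubjectRecord

# Printed percent-body-fat regression coefficients for the conventional
# feature set (age, gender, height, weight, H^2/R50) with intercept 59.6240.
PRINTED_CONV = {
    "intercept": 59.6240,
    "age_yr": -0.0992,
    "gender": 7.4604,
    "height_cm": -0.4174,
    "weight_kg": 0.4673,
    "h2_over_r50": -0.4217,
}


def _subject(**overrides):
    base = dict(
        id="S0", group="male:General", gender=0,
        height_cm=178.0, age_yr=21.3, weight_kg=83.6,
        waist_cm=83.5, hip_cm=100.7, true_pbf_pct=17.9,
        ref_wholebody_r50_ohms=550.0, ref_h2r=178.0**2 / 550.0,
        finger_ohms=585.0, upper_series=None,
    )
    base.update(overrides)
    return SubjectRecord(**base)


class TestBuildFeatures:
    def test_h2_over_imp_arithmetic(self):
        v = build_features(_subject(), 600.0, "NET1_M2")
        assert v[-1] == pytest.approx(178.0**2 / 600.0, abs=1e-3)  # 52.8067

    def test_waist_hip_ratio_arithmetic(self):
        v = build_features(_subject(), 600.0, "NET1_M3")
        assert v[-1] == pytest.approx(0.82920, abs=1e-4)

    def test_gender_encoding(self):
        v = build_features(_subject(gender=1), None, "CONV5", h2r=50.0)
        assert v[2] == 1.0

    def test_model_variants_differ_only_by_waist_hip(self):
        m2 = FEATURE_SETS["NET1_M2"].features
        m3 = FEATURE_SETS["NET1_M3"].features
        assert m3[: len(m2)] == m2
        assert set(m3) - set(m2) == {"waist_hip_ratio"}

    def test_missing_h2r_raises_schema_error(self):
        with pytest.raises(SchemaError, match="h2_over_r50"):
            build_features(_subject(), 600.0, "NET2_CONV")

    def test_missing_settled_raises_schema_error(self):
        with pytest.raises(SchemaError, match="r50_prop"):
            build_features(_subject(), None, "NET1_M1")


class TestPredictLinear:
    def _printed_model(self):
        names = ("age_yr", "gender", "height_cm", "weight_kg", "h2_over_r50")
        coef = np.array([PRINTED_CONV[n] for n in names])
        return LinearModel(
            feature_names=names, intercept=PRINTED_CONV["intercept"],
            coefficients=coef, std_errors=np.zeros(5), p_values=np.zeros(5),
            intercept_std_error=0.0, intercept_p_value=0.0, n_fit=163,
        )

    def test_intercept_at_zero_features(self):
        assert predict_linear(self._printed_model(), np.zeros(5)) == 59.6240

    def test_printed_coefficients_dot_product(self):
        x = np.array([20.0, 1.0, 170.0, 60.0, 50.0])
        assert predict_linear(self._printed_model(), x) == pytest.approx(
            1.0954, abs=1e-4
        )

    def test_zero_coefficients_return_intercept(self):
        m = replace(self._printed_model(), coefficients=np.zeros(5))
        assert predict_linear(m, np.array([1.0, 2, 3, 4, 5])) == 59.6240

    def test_exact_affinity(self):
        m = self._printed_model()
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=5), rng.normal(size=5)
        for alpha in (0.0, 0.3, 1.0):
            mix = alpha * x + (1 - alpha) * y
            assert predict_linear(m, mix) == pytest.approx(
                alpha * predict_linear(m, x) + (1 - alpha) * predict_linear(m, y),
                rel=1e-12,
            )

    def test_length_mismatch(self):
        with pytest.raises(SchemaError):
            predict_linear(self._printed_model(), np.zeros(4))


class TestFitOLS:
    def test_exact_line(self):
        x = np.arange(10.0)[:, None]
        m = fit_ols(x, 2.0 * x.ravel() + 1.0)
        assert m.coefficients[0] == pytest.approx(2.0, abs=1e-10)
        assert m.intercept == pytest.approx(1.0, abs=1e-10)

    def test_recovers_known_coefficients(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 8))
        beta = rng.normal(size=8)
        y = 0.7 + X @ beta
        m = fit_ols(X, y)
        # oracle: normal equations solved independently
        A = np.column_stack([np.ones(len(X)), X])
        ref = np.linalg.solve(A.T @ A, A.T @ y)
        np.testing.assert_allclose(m.coefficients, beta, atol=1e-8)
        np.testing.assert_allclose(m.coefficients, ref[1:], atol=1e-10)

    def test_null_feature_p_value_distribution(self):
        """A pure-noise column should rarely look significant."""
        rng = np.random.default_rng(99)
        high_p = 0
        for _ in range(100):
            X = rng.normal(size=(80, 3))
            y = 1.0 + X[:, 0] - 2.0 * X[:, 1] + rng.normal(0, 1.0, 80)
            X_aug = np.column_stack([X, rng.normal(size=80)])
            m = fit_ols(X_aug, y)
            high_p += m.p_values[-1] > 0.05
        assert high_p >= 90

    def test_rank_deficiency(self):
        X = np.ones((20, 2))
        X[:, 1] = 2.0  # constant columns collinear with intercept
        with pytest.raises(SingularDesignError):
            fit_ols(X, np.arange(20.0))

    def test_nested_model_training_r2_never_decreases(self, default_cohort):
        # slice spanning both genders so the gender column is informative
        subjects = default_cohort[80:160]
        h2r = {s.id: s.ref_h2r for s in subjects}
        y = np.array([s.true_pbf_pct for s in subjects])
        X5 = build_feature_matrix(subjects, None, "CONV5", h2r)
        X8 = build_feature_matrix(subjects, None, "PROP8", h2r)

        def train_r2(X):
            m = fit_ols(X, y)
            resid = y - predict_linear(m, X)
            return 1.0 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))

        assert train_r2(X8) >= train_r2(X5) - 1e-12

    def test_serialization_round_trip(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 3))
        m = fit_ols(X, X @ [1.0, 2.0, 3.0] + rng.normal(size=30))
        m2 = LinearModel.from_json(m.to_json())
        x = rng.normal(size=3)
        assert predict_linear(m, x) == predict_linear(m2, x)


def _linear_task(n=500, p=5, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    beta = rng.normal(size=p)
    y = 2.0 + X @ beta + (rng.normal(0, noise, n) if noise else 0.0)
    return X, y


class TestMLP:
    SPEC = MLPSpec(input_dim=5, hidden_nodes=32, seed=0)

    def test_learns_noise_free_linear_target(self):
        X, y = _linear_task()
        model = train_mlp(self.SPEC, X, y)
        Xh, yh = _linear_task(seed=0)  # same distribution, training points
        pred = predict_mlp(model, Xh)
        ss = np.sum((yh - pred) ** 2) / np.sum((yh - yh.mean()) ** 2)
        assert 1.0 - ss >= 0.99

    def test_seeded_training_is_deterministic(self):
        X, y = _linear_task(n=120)
        a = train_mlp(self.SPEC, X, y)
        b = train_mlp(self.SPEC, X, y)
        assert a.stopped_epoch == b.stopped_epoch
        x = np.zeros(5)
        assert predict_mlp(a, x) == predict_mlp(b, x)

    def test_early_stopping_engages_on_pure_noise(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(100, 5))
        y = rng.normal(size=100)
        spec = replace(self.SPEC, patience=10)
        model = train_mlp(spec, X, y)
        assert model.stopped_epoch < spec.max_epochs
        assert len(model.history) == model.stopped_epoch

    def test_restores_best_validation_weights(self):
        X, y = _linear_task(n=100, noise=1.0)
        model = train_mlp(replace(self.SPEC, patience=20), X, y)
        best_epoch = min(model.history, key=lambda h: h[2])[0]
        assert best_epoch <= model.stopped_epoch

    def test_batch_prediction_equals_rowwise(self):
        X, y = _linear_task(n=60)
        model = train_mlp(replace(self.SPEC, max_epochs=200, patience=20), X, y)
        batch = predict_mlp(model, X[:7])
        rows = [predict_mlp(model, X[i]) for i in range(7)]
        # matrix and vector paths reduce in different BLAS orders
        np.testing.assert_allclose(batch, rows, rtol=1e-10)

    def test_dim_mismatch(self):
        X, y = _linear_task(n=40)
        model = train_mlp(replace(self.SPEC, max_epochs=150, patience=10), X, y)
        with pytest.raises(SchemaError):
            predict_mlp(model, np.zeros(4))

    def test_zero_weights_output_final_bias(self):
        spec = MLPSpec(input_dim=3, hidden_nodes=4, seed=0)
        weights = [np.zeros((3, 4)), np.zeros((4, 4)), np.zeros((4, 4)), np.zeros((4, 1))]
        biases = [np.zeros(4), np.zeros(4), np.zeros(4), np.array([2.5])]
        model = TrainedModel(
            spec=spec, weights=weights, biases=biases,
            x_mean=np.zeros(3), x_sd=np.ones(3), y_mean=0.0, y_sd=1.0,
            history=[], stopped_epoch=0,
        )
        assert predict_mlp(model, np.array([4.0, -1.0, 7.0])) == 2.5

    def test_standardization_identity_on_pre_standardized_data(self):
        """Training on externally standardized data with the flag off matches
        flag-on training on the raw data (same split, same seed)."""
        X, y = _linear_task(n=100, noise=0.5, seed=7)
        spec = replace(self.SPEC, max_epochs=100, patience=99)
        rng = np.random.default_rng(spec.seed)
        order = rng.permutation(len(X))
        n_val = max(1, int(round(spec.validation_fraction * len(X))))
        vi, ti = order[:n_val], order[n_val:]
        m_on = _fit_network(spec, X[ti], y[ti], X[vi], y[vi],
                            np.random.default_rng(spec.seed))
        xm, xs = X[ti].mean(axis=0), X[ti].std(axis=0)
        ym, ys = y[ti].mean(), y[ti].std()
        Xs, ys_ = (X - xm) / xs, (y - ym) / ys
        m_off = _fit_network(replace(spec, standardize=False),
                             Xs[ti], ys_[ti], Xs[vi], ys_[vi],
                             np.random.default_rng(spec.seed))
        probe = np.random.default_rng(1).normal(size=(10, 5))
        on = predict_mlp(m_on, probe)
        off = predict_mlp(m_off, (probe - xm) / xs) * ys + ym
        np.testing.assert_allclose(on, off, rtol=1e-9, atol=1e-9)

    def test_serialization_round_trip(self):
        X, y = _linear_task(n=60)
        model = train_mlp(replace(self.SPEC, max_epochs=150, patience=10), X, y)
        clone = TrainedModel.from_json(model.to_json())
        probe = np.random.default_rng(2).normal(size=(5, 5))
        np.testing.assert_array_equal(predict_mlp(model, probe),
                                      predict_mlp(clone, probe))

    def test_cv_ensemble_deterministic_and_averaging(self):
        X, y = _linear_task(n=80, noise=0.5)
        spec = replace(self.SPEC, max_epochs=120, patience=20)
        ens1 = train_mlp_cv_ensemble(spec, X, y, n_folds=4)
        ens2 = train_mlp_cv_ensemble(spec, X, y, n_folds=4)
        probe = np.random.default_rng(3).normal(size=(6, 5))
        np.testing.assert_array_equal(
            predict_mlp_ensemble(ens1, probe), predict_mlp_ensemble(ens2, probe)
        )
        members = np.array([predict_mlp(m, probe) for m in ens1])
        np.testing.assert_allclose(
            predict_mlp_ensemble(ens1, probe), members.mean(axis=0), rtol=1e-12
        )


class TestH2REstimation:
    def test_regression_exact_on_linear_ground_truth(self):
        """When the cylinder index is an exact affine function of the five
        upper-body features, the regression variant recovers it perfectly."""
        rng = np.random.default_rng(12)
        subjects, settled = [], {}
        for i in range(60):
            h = rng.uniform(150, 195)
            a = rng.uniform(18, 30)
            g = int(rng.integers(0, 2))
            w = rng.uniform(50, 100)
            r50 = rng.uniform(900, 1500)
            h2r = 10.0 + 0.3 * h - 0.1 * a + 2.0 * g + 0.2 * w - 0.01 * r50
            subjects.append(_subject(id=f"S{i}", gender=g, height_cm=h,
                                     age_yr=a, weight_kg=w, ref_h2r=h2r))
            settled[f"S{i}"] = r50
        model = fit_h2r_model(subjects, settled, H2RVariant.REGRESSION)
        pred = estimate_h2r(subjects, settled, model)
        ref = np.array([s.ref_h2r for s in subjects])
        np.testing.assert_allclose(pred, ref, atol=1e-8)

    def test_unfitted_model_raises(self):
        from wristbia.models import H2RModel
        bad = H2RModel(H2RVariant.REGRESSION, FEATURE_SETS["NET1_M1"])
        with pytest.raises(Exception, match="not fitted"):
            estimate_h2r([_subject()], {"S0": 600.0}, bad)
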