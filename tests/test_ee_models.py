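"""Relative-error MLR (closed form vs numerical oracle), ANN ensemble
training, and bundle fitting/routing."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from iscee.ee_models import (
    AnnTrainConfig,
    bundle_from_dict,
    bundle_to_dict,
    fit_ann_ensemble,
    fit_bundle,
    fit_relative_mlr,
    predict_bundle,
    predict_mlr,
    relative_sse,
)
from iscee.presets import MLR_CLASS_FEATURES, MLR_DIRECT_FEATURES


def _table(X):
    return pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])


def _numeric_objective(X, y):
    A = np.column_stack([np.ones(len(y)), X])

    def obj(beta):
        return np.sum(((A @ beta - y) / y) ** 2)

    return obj


class TestRelativeMlr:
    def test_exact_linear_target_recovered(self, rng):
        X = rng.normal(size=(30, 3))
        y = 2000.0 + X @ np.array([50.0, -30.0, 10.0])
        assert np.all(y > 0)
        m = fit_relative_mlr(_table(X), y, ["f0", "f1", "f2"])
        np.testing.assert_allclose(predict_mlr(m, _table(X)), y, rtol=1e-8)
        assert m.intercept == pytest.approx(2000.0, rel=1e-6)

    def test_intercept_only_equal_targets(self):
        X = np.empty((5, 0))
        y = np.full(5, 1234.5)
        m = fit_relative_mlr(pd.DataFrame(index=range(5)), y, [])
        assert m.intercept == pytest.approx(1234.5)

    def test_nonpositive_target_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        y = np.array([1.0] * 9 + [-1.0])
        with pytest.raises(ValueError, match="positive"):
            fit_relative_mlr(_table(X), y, ["f0", "f1"])

    def test_collinear_features_named(self, rng):
        X = rng.normal(size=(20, 1))
        X = np.column_stack([X, 2 * X])
        with pytest.raises(ValueError, match="collinear"):
            fit_relative_mlr(_table(X), np.full(20, 100.0), ["f0", "f1"])

    @pytest.mark.parametrize("seed", range(10))
    def test_closed_form_matches_numerical_minimizer(self, seed):
        rng = np.random.default_rng(seed)
        n, p = 30, 3
        X = rng.normal(size=(n, p))
        y = np.exp(rng.normal(7.5, 0.3, size=n))  # positive, EE-scaled
        m = fit_relative_mlr(_table(X), y, [f"f{i}" for i in range(p)])
        obj = _numeric_objective(X, y)
        ours = relative_sse(m, _table(X), y)
        # independent derivative-free minimizer started at the OLS solution
        ols = np.linalg.lstsq(np.column_stack([np.ones(n), X]), y, rcond=None)[0]
        res = optimize.minimize(obj, ols, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-14,
                                         "maxiter": 20000, "maxfev": 20000})
        assert ours <= res.fun + 1e-6 * max(1.0, res.fun)
        assert abs(ours - res.fun) <= 1e-6 * max(1.0, res.fun)

    def test_relative_objective_beats_ols_solution(self, rng):
        n = 50
        X = rng.normal(size=(n, 2))
        y = np.exp(rng.normal(7.0, 0.5, size=n))
        feats = ["f0", "f1"]
        m = fit_relative_mlr(_table(X), y, feats)
        ols = np.linalg.lstsq(np.column_stack([np.ones(n), X]), y, rcond=None)[0]
        from iscee.ee_models import MlrModel
        ols_model = MlrModel(intercept=float(ols[0]),
                             coefficients=dict(zip(feats, ols[1:])))
        assert relative_sse(m, _table(X), y) <= relative_sse(ols_model, _table(X), y) + 1e-12

    def test_equal_targets_reduce_to_ols(self, rng):
        # constant y makes the 1/y^2 weights uniform
        n = 40
        X = rng.normal(size=(n, 2))
        y = np.full(n, 2000.0)
        m = fit_relative_mlr(_table(X), y, ["f0", "f1"])
        ols = np.linalg.lstsq(np.column_stack([np.ones(n), X]), y, rcond=None)[0]
        np.testing.assert_allclose([m.intercept, *m.coefficients.values()], ols,
                                   atol=1e-8)

    def test_parameter_recovery_multiplicative_noise(self):
        rng = np.random.default_rng(42)
        n = 500
        # balanced two-level design: every coefficient is well identified
        X = rng.choice([-1.0, 1.0], size=(n, 3))
        beta = np.array([3000.0, 800.0, 700.0, 600.0])
        y = (beta[0] + X @ beta[1:]) * (1 + 0.05 * rng.standard_normal(n))
        m = fit_relative_mlr(_table(X), y, ["f0", "f1", "f2"])
        est = np.array([m.intercept, *m.coefficients.values()])
        np.testing.assert_allclose(est, beta, rtol=0.02)

    def test_predict_missing_feature_errors(self, rng):
        X = rng.normal(size=(10, 2))
        m = fit_relative_mlr(_table(X), np.full(10, 100.0) + X[:, 0], ["f0", "f1"])
        with pytest.raises(KeyError):
            predict_mlr(m, pd.DataFrame({"f0": [1.0]}))


class TestAnnEnsemble:
    def test_learns_linear_function(self, rng):
        n = 200
        X = rng.uniform(-1, 1, size=(n, 2))
        y = 2000 + 300 * X[:, 0] - 150 * X[:, 1]
        cfg = AnnTrainConfig(hidden_units=3, ensemble_size=5, max_epochs=200)
        m = fit_ann_ensemble(_table(X), y, ["f0", "f1"], cfg, seed=0)
        Xh = rng.uniform(-1, 1, size=(100, 2))
        yh = 2000 + 300 * Xh[:, 0] - 150 * Xh[:, 1]
        pred = m.predict(_table(Xh))
        ss_res = np.sum((pred - yh) ** 2)
        ss_tot = np.sum((yh - yh.mean()) ** 2)
        assert 1 - ss_res / ss_tot > 0.99

    def test_deterministic_given_seed(self, rng):
        X = rng.uniform(-1, 1, size=(60, 2))
        y = 1500 + 100 * X[:, 0] + 20 * rng.standard_normal(60)
        y = np.abs(y)
        cfg = AnnTrainConfig(hidden_units=3, ensemble_size=3, max_epochs=50)
        m1 = fit_ann_ensemble(_table(X), y, ["f0", "f1"], cfg, seed=7)
        m2 = fit_ann_ensemble(_table(X), y, ["f0", "f1"], cfg, seed=7)
        np.testing.assert_array_equal(m1.predict(_table(X)), m2.predict(_table(X)))

    def test_ensemble_averaging_reduces_error(self, rng):
        # variance-reduction property: a 10-net ensemble should rarely lose
        # to a single net on held-out data
        n = 150
        wins = 0
        trials = 10
        for seed in range(trials):
            r = np.random.default_rng(seed)
            X = r.uniform(-1, 1, size=(n, 2))
            y = 1800 + 250 * np.tanh(2 * X[:, 0]) + 100 * X[:, 1] ** 2 \
                + 40 * r.standard_normal(n)
            Xh = r.uniform(-1, 1, size=(80, 2))
            yh = 1800 + 250 * np.tanh(2 * Xh[:, 0]) + 100 * Xh[:, 1] ** 2
            small = AnnTrainConfig(hidden_units=3, ensemble_size=1, max_epochs=60)
            big = AnnTrainConfig(hidden_units=3, ensemble_size=10, max_epochs=60)
            e1 = np.mean((fit_ann_ensemble(_table(X), y, ["f0", "f1"], small,
                                           seed=seed).predict(_table(Xh)) - yh) ** 2)
            e10 = np.mean((fit_ann_ensemble(_table(X), y, ["f0", "f1"], big,
                                            seed=seed).predict(_table(Xh)) - yh) ** 2)
            wins += e10 <= e1
        assert wins >= 8


def _bundle_table(rng, n_subjects=6, per_class=8):
    """Small synthetic feature table with linear per-class EE structure."""
    rows = []
    classes = ["sedentary", "low_intensity", "high_intensity", "walking"]
    base = {"sedentary": 1700, "low_intensity": 3500,
            "high_intensity": 6000, "walking": 6500}
    for sid in range(n_subjects):
        ree = 1500 + 100 * rng.standard_normal()
        for cls in classes:
            for i in range(per_class):
                x = rng.uniform(0.5, 2.0)
                rows.append({
                    "subject_id": f"s{sid}", "activity_name": cls, "activity_class": cls,
                    "ee_meas": base[cls] * x * (1 + 0.02 * rng.standard_normal()),
                    "x": x, "ree": ree,
                })
    return pd.DataFrame(rows)


class TestBundles:
    def test_class_conditional_preset_feature_keys(self, cohort_table):
        table, _ = cohort_table
        bundle = fit_bundle(table, "class_conditional", "mlr")
        for cls, feats in MLR_CLASS_FEATURES.items():
            assert list(bundle.models[cls].coefficients.keys()) == list(feats)

    def test_direct_preset_feature_keys(self, cohort_table):
        table, _ = cohort_table
        bundle = fit_bundle(table, "direct", "mlr")
        assert list(bundle.models["direct"].coefficients.keys()) == \
            list(MLR_DIRECT_FEATURES)

    def test_architecture_feature_shape_mismatch(self, cohort_table):
        table, _ = cohort_table
        with pytest.raises(ValueError, match="flat feature list"):
            fit_bundle(table, "direct", "mlr", feature_sets=MLR_CLASS_FEATURES)
        with pytest.raises(ValueError, match="per-class mapping"):
            fit_bundle(table, "class_conditional", "mlr",
                       feature_sets=list(MLR_DIRECT_FEATURES))

    def test_true_label_routing_on_perfect_models(self, rng):
        table = _bundle_table(rng)
        sets = {c: ["x", "ree"] for c in
                ("sedentary", "low_intensity", "high_intensity", "walking")}
        bundle = fit_bundle(table, "class_conditional", "mlr", feature_sets=sets,
                            fit_classifier=False)
        pred = predict_bundle(bundle, table, class_source="true_label")
        pct = np.abs(pred - table["ee_meas"]) / table["ee_meas"]
        assert np.mean(pct) < 0.05

    def test_misrouted_window_uses_wrong_model(self, rng):
        table = _bundle_table(rng)
        sets = {c: ["x", "ree"] for c in
                ("sedentary", "low_intensity", "high_intensity", "walking")}
        bundle = fit_bundle(table, "class_conditional", "mlr", feature_sets=sets,
                            fit_classifier=False)
        row = table[table["activity_class"] == "sedentary"].head(1).copy()
        honest = predict_bundle(bundle, row, class_source="true_label")[0]
        row["activity_class"] = "walking"  # deliberate misroute: no correction
        wrong = predict_bundle(bundle, row, class_source="true_label")[0]
        assert abs(wrong - honest) > 500

    def test_bundle_json_round_trip(self, rng):
        table = _bundle_table(rng)
        sets = {c: ["x", "ree"] for c in
                ("sedentary", "low_intensity", "high_intensity", "walking")}
        bundle = fit_bundle(table, "class_conditional", "mlr", feature_sets=sets,
                            classifier_config=None, fit_classifier=False)
        back = bundle_from_dict(bundle_to_dict(bundle))
        np.testing.assert_allclose(
            predict_bundle(back, table, "true_label"),
            predict_bundle(bundle, table, "true_label"))

    def test_small_class_rejected(self, rng):
        table = _bundle_table(rng, n_subjects=1, per_class=2)
        sets = {c: ["x", "ree", "ree"] for c in
                ("sedentary", "low_intensity", "high_intensity", "walking")}
        with pytest.raises(ValueError, match="windows"):
            fit_bundle(table, "class_conditional", "mlr", feature_sets=sets,
                       fit_classifier=False)
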