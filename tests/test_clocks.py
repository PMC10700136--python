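"""Bagged LASSO clocks: oracle equivalence, tuning rule, training, prediction."""

import numpy as np
import pandas as pd
import pytest

from helpers import lasso_coordinate_descent
from organclocks import (
    ClockConfig,
    ClockModel,
    CohortData,
    fit_lasso,
    lambda_grid,
    predict_age,
    select_lambda,
    train_bagged_clock,
)


def _single_standardized_predictor(n=200, rho=0.8, seed=0):
    """x population-standardized with x'y/n = rho and y mean-free."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    x = (x - x.mean()) / x.std()
    resid = rng.normal(size=n)
    resid -= resid.mean()
    resid -= x * (x @ resid) / n  # orthogonalize to x
    y = rho * x + resid
    return x[:, None], y


class TestFitLasso:
    def test_soft_threshold_closed_form(self):
        X, y = _single_standardized_predictor(rho=0.8)
        beta, _ = fit_lasso(X, y, lam=0.3)
        assert beta[0] == pytest.approx(0.8 - 0.3, abs=1e-6)

    def test_lambda_above_max_gives_null_model(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(50, 4))
        y = rng.normal(size=50) + 70
        lam_max = np.abs(X.T @ (y - y.mean())).max() / len(y)
        beta, intercept = fit_lasso(X, y, lam=lam_max * 1.01)
        assert np.all(beta == 0)
        assert intercept == pytest.approx(y.mean(), abs=1e-9)

    def test_lambda_zero_matches_normal_equations(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(60, 5))
        y = X @ rng.normal(size=5) + rng.normal(size=60)
        beta, intercept = fit_lasso(X, y, lam=0.0)
        Xd = np.column_stack([np.ones(60), X])
        full = np.linalg.solve(Xd.T @ Xd, Xd.T @ y)
        np.testing.assert_allclose(np.r_[intercept, beta], full, atol=1e-6)

    @pytest.mark.parametrize("lam", [0.01, 0.1, 0.5])
    def test_matches_coordinate_descent_oracle(self, lam):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 5))
        y = X @ np.array([1.0, -0.5, 0.0, 0.3, 0.0]) + rng.normal(size=40)
        beta, b0 = fit_lasso(X, y, lam)
        beta_o, b0_o = lasso_coordinate_descent(X, y, lam)
        np.testing.assert_allclose(beta, beta_o, atol=1e-6)
        assert b0 == pytest.approx(b0_o, abs=1e-6)

    def test_sparsity_monotone_in_lambda(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(80, 10))
        y = X @ rng.normal(size=10) + rng.normal(size=80)
        grid = lambda_grid(X, y, n_lambdas=25)
        nnz = [np.count_nonzero(fit_lasso(X, y, lam)[0]) for lam in grid]
        assert all(a <= b for a, b in zip(nnz, nnz[1:]))  # grid is descending

    def test_nonfinite_input_raises(self):
        with pytest.raises(ValueError, match="non-finite"):
            fit_lasso(np.array([[np.nan], [1.0]]), np.array([1.0, 2.0]), 0.1)


class TestSelectLambda:
    def test_retention_rule_fixture(self):
        lams = np.array([1.0, 0.1, 0.01])
        scores = np.array([0.90, 0.95, 0.96])
        # 0.95 >= 0.95 * 0.96 = 0.912, and 0.90 < 0.912
        assert select_lambda(lams, scores, 0.95) == 0.1

    def test_all_equal_scores_pick_sparsest(self):
        lams = np.array([1.0, 0.1, 0.01])
        assert select_lambda(lams, np.array([0.5, 0.5, 0.5]), 0.95) == 1.0

    def test_retention_one_returns_largest_maximizer(self):
        lams = np.array([1.0, 0.1, 0.01])
        assert select_lambda(lams, np.array([0.2, 0.9, 0.9]), 1.0) == 0.1

    def test_nonpositive_best_returns_argmax_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            out = select_lambda(np.array([1.0, 0.1]), np.array([-0.5, -0.1]), 0.95)
        assert out == 0.1
        assert "arg-max" in caplog.text

    def test_empty_grid_raises(self):
        with pytest.raises(ValueError, match="empty"):
            select_lambda(np.array([]), np.array([]))

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        lams = np.sort(rng.uniform(0.001, 1.0, 12))[::-1]
        scores = rng.uniform(0.1, 1.0, 12)
        chosen = select_lambda(lams, scores, 0.95)
        eligible = [l for l, s in zip(lams, scores) if s >= 0.95 * scores.max()]
        assert chosen == max(eligible)


class TestTrainPredict:
    def test_planted_signal_recovered_on_held_out_data(self, planted_cohort):
        train = planted_cohort.subset(planted_cohort.meta.index < 200)
        test = planted_cohort.subset(planted_cohort.meta.index >= 200)
        cfg = ClockConfig(n_bootstraps=10, n_lambdas=25, seed=1)
        model = train_bagged_clock(train, ["p0", "p1", "p2"], cfg, "toy")
        pred = predict_age(model, test)
        r = np.corrcoef(pred.mean_prediction, test.age)[0, 1]
        assert r > 0.99

    def test_training_is_deterministic_given_seed(self, planted_cohort):
        cfg = ClockConfig(n_bootstraps=4, n_lambdas=20, seed=5)
        m1 = train_bagged_clock(planted_cohort, ["p0", "p1", "p2"], cfg, "a")
        m2 = train_bagged_clock(planted_cohort, ["p0", "p1", "p2"], cfg, "a")
        np.testing.assert_array_equal(m1.coefs, m2.coefs)
        np.testing.assert_array_equal(m1.bootstrap_indices, m2.bootstrap_indices)

    def test_ensemble_mean_is_arithmetic_mean_and_order_invariant(self, planted_cohort):
        cfg = ClockConfig(n_bootstraps=6, n_lambdas=20, seed=2)
        model = train_bagged_clock(planted_cohort, ["p0", "p1"], cfg, "a")
        pred = predict_age(model, planted_cohort)
        np.testing.assert_allclose(
            pred.mean_prediction, pred.instance_predictions.mean(axis=1)
        )
        shuffled = ClockModel(
            model_name=model.model_name,
            probes=model.probes,
            feature_means=model.feature_means,
            feature_sds=model.feature_sds,
            coefs=model.coefs[::-1].copy(),
            intercepts=model.intercepts[::-1].copy(),
            lambdas=model.lambdas[::-1].copy(),
            bootstrap_indices=model.bootstrap_indices[::-1].copy(),
            config=model.config,
            n_train=model.n_train,
        )
        np.testing.assert_allclose(
            predict_age(shuffled, planted_cohort).mean_prediction, pred.mean_prediction
        )

    def test_all_zero_coefficients_predict_intercept_plus_sex(self, planted_cohort):
        model = ClockModel(
            model_name="null", probes=["p0"],
            feature_means=np.array([0.0]), feature_sds=np.array([1.0]),
            coefs=np.array([[0.0, 2.0], [0.0, 2.0]]),
            intercepts=np.array([70.0, 74.0]),
            lambdas=np.array([1.0, 1.0]),
            bootstrap_indices=np.zeros((2, 1), dtype=np.int64),
            config=ClockConfig(n_bootstraps=2),
        )
        pred = predict_age(model, planted_cohort)
        expected = 72.0 + 2.0 * planted_cohort.sex
        np.testing.assert_allclose(pred.mean_prediction, expected)

    def test_missing_probe_raises_with_names(self, planted_cohort):
        cfg = ClockConfig(n_bootstraps=2, n_lambdas=10, seed=0)
        model = train_bagged_clock(planted_cohort, ["p0"], cfg, "a")
        model.probes = ["nope"]
        with pytest.raises(ValueError, match="nope"):
            predict_age(model, planted_cohort)

    def test_zero_variance_probe_named_in_error(self, planted_cohort):
        cohort = CohortData(
            planted_cohort.proteins.assign(flat=1.0), planted_cohort.meta
        )
        with pytest.raises(ValueError, match="flat"):
            train_bagged_clock(cohort, ["p0", "flat"], ClockConfig(n_bootstraps=1), "a")

    def test_too_few_subjects_for_cv_raises(self, planted_cohort):
        tiny = planted_cohort.subset(planted_cohort.meta.index < 3)
        with pytest.raises(ValueError, match="cv_folds"):
            train_bagged_clock(tiny, ["p0"], ClockConfig(n_bootstraps=1, cv_folds=5), "a")

    def test_json_round_trip_is_lossless(self, planted_cohort):
        cfg = ClockConfig(n_bootstraps=3, n_lambdas=15, seed=8)
        model = train_bagged_clock(planted_cohort, ["p0", "p1"], cfg, "rt")
        back = ClockModel.from_json(model.to_json())
        np.testing.assert_array_equal(model.coefs, back.coefs)
        np.testing.assert_array_equal(model.feature_means, back.feature_means)
        np.testing.assert_array_equal(model.bootstrap_indices, back.bootstrap_indices)
        assert back.config == model.config and back.probes == model.probes
        np.testing.assert_allclose(
            predict_age(back, planted_cohort).mean_prediction,
            predict_age(model, planted_cohort).mean_prediction,
        )


class TestCohortData:
    def test_rejects_missing_protein_values(self):
        proteins = pd.DataFrame({"p0": [1.0, np.nan]})
        meta = pd.DataFrame({"age": [50.0, 60.0], "sex": [0, 1], "cohort": "x"})
        with pytest.raises(ValueError, match="missing"):
            CohortData(proteins, meta)

    def test_rejects_bad_sex_coding(self):
        proteins = pd.DataFrame({"p0": [1.0, 2.0]})
        meta = pd.DataFrame({"age": [50.0, 60.0], "sex": [2, 1], "cohort": "x"})
        with pytest.raises(ValueError, match="F=1"):
            CohortData(proteins, meta)
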