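"""Univariate/stepwise OLS, leverage screening and fit statistics, each
checked against an independent route (statsmodels or a brute-force loop)."""

import numpy as np
import pytest
import statsmodels.api as sm

import sludgeqspr as sq
from sludgeqspr.linear import loo_press_ols


class TestUnivariate:
    def test_exact_line_recovered(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        m = sq.fit_univariate(x, 2 * x + 1)
        assert m.slope == pytest.approx(2.0, abs=1e-12)
        assert m.intercept == pytest.approx(1.0, abs=1e-12)
        assert m.r2 == pytest.approx(1.0)

    def test_constant_response(self):
        m = sq.fit_univariate([0.0, 1.0, 2.0], [5.0, 5.0, 5.0])
        assert m.slope == 0.0 and m.r2 == 0.0

    def test_zero_variance_predictor_rejected(self):
        with pytest.raises(ValueError):
            sq.fit_univariate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_matches_statsmodels(self, rng):
        x = rng.standard_normal(60)
        y = 0.4 * x + rng.standard_normal(60)
        m = sq.fit_univariate(x, y)
        ref = sm.OLS(y, sm.add_constant(x)).fit()
        assert m.intercept == pytest.approx(ref.params[0])
        assert m.slope == pytest.approx(ref.params[1])
        assert m.r2 == pytest.approx(ref.rsquared)


class TestLeverage:
    def test_extreme_point_flagged(self, rng):
        x = np.concatenate([rng.normal(0, 1, 40), [15.0]])
        y = 0.5 * x + rng.normal(0, 0.2, 41)
        rep = sq.leverage_filter_refit(x, y, multiplier=3)
        assert 40 in rep.flagged
        # brute-force hat diagonal of [1, x]
        A = np.column_stack([np.ones(41), x])
        H = A @ np.linalg.inv(A.T @ A) @ A.T
        np.testing.assert_allclose(rep.leverages, np.diag(H), atol=1e-10)
        assert np.argmax(rep.leverages) == 40

    def test_hat_trace_equals_parameter_count(self, rng):
        X = rng.standard_normal((30, 4))
        assert sq.hat_diagonal(X).sum() == pytest.approx(5.0)
        assert np.all((sq.hat_diagonal(X) >= 0) & (sq.hat_diagonal(X) <= 1))

    def test_no_flag_is_noop(self, rng):
        x = np.linspace(-1, 1, 20)
        y = x + rng.normal(0, 0.1, 20)
        rep = sq.leverage_filter_refit(x, y, multiplier=3)
        assert rep.flagged.size == 0
        full = sq.fit_ols(x[:, None], y)
        np.testing.assert_allclose(rep.model.coef, full.coef)


class TestStepwise:
    def test_strong_single_effect_enters_first(self, rng):
        X = rng.standard_normal((200, 10))
        y = 2.0 * X[:, 4] + 0.5 * rng.standard_normal(200)
        model, selected = sq.stepwise_regression(X, y, 0.15, 0.15)
        assert selected[0] == "x4"
        # its single-variable p-value is indeed the smallest
        pvals = [
            sm.OLS(y, sm.add_constant(X[:, j])).fit().pvalues[1] for j in range(10)
        ]
        assert int(np.argmin(pvals)) == 4

    def test_pure_noise_rarely_enters_at_strict_alpha(self):
        empty = 0
        for seed in range(40):
            r = np.random.default_rng(seed)
            X = r.standard_normal((200, 10))
            y = r.standard_normal(200)
            _, selected = sq.stepwise_regression(X, y, 0.001, 0.001)
            empty += not selected
        assert empty >= 38  # family-wise entry chance ~ 10 * 0.001 per step

    def test_duplicated_column_enters_once(self, rng):
        x = rng.standard_normal(100)
        X = np.column_stack([x, x, rng.standard_normal(100)])
        y = 3 * x + 0.1 * rng.standard_normal(100)
        _, selected = sq.stepwise_regression(X, y, 0.15, 0.15)
        assert ("x0" in selected) != ("x1" in selected)


class TestFitMetrics:
    def test_perfect_predictions(self):
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        m = sq.fit_metrics(y, y, n_params=1)
        assert m.r2 == pytest.approx(1.0) and m.mue == 0.0

    def test_null_model_r2_zero(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        m = sq.fit_metrics(y, np.full(4, y.mean()), n_params=0)
        assert m.r2 == pytest.approx(0.0)

    def test_r2_pred_equals_bruteforce_loo(self, rng):
        X = rng.standard_normal((40, 3))
        y = X @ [1.0, 0.5, -1.0] + rng.standard_normal(40)
        press = loo_press_ols(X, y)
        # brute force: refit n times
        press_bf = 0.0
        for i in range(40):
            mask = np.ones(40, dtype=bool)
            mask[i] = False
            m = sq.fit_ols(X[mask], y[mask])
            press_bf += (y[i] - m.predict(X[i : i + 1])[0]) ** 2
        assert press == pytest.approx(press_bf)
        model = sq.fit_ols(X, y)
        met = sq.fit_metrics(y, model.predict(X), n_params=3, press=press)
        sst = np.sum((y - y.mean()) ** 2)
        assert met.r2_pred == pytest.approx(1 - press_bf / sst)
        assert met.r2_adj <= met.r2

    def test_small_sample_flagged(self):
        m = sq.fit_metrics([1.0, 2.0], [1.1, 1.9], n_params=2)
        assert m.small_sample and m.r2_adj is None and m.s is None

    def test_matches_statsmodels_summary(self, rng):
        X = rng.standard_normal((50, 2))
        y = X @ [1.0, -1.0] + rng.standard_normal(50)
        model = sq.fit_ols(X, y)
        met = sq.fit_metrics(y, model.predict(X), n_params=2)
        ref = sm.OLS(y, sm.add_constant(X)).fit()
        assert met.r2 == pytest.approx(ref.rsquared)
        assert met.r2_adj == pytest.approx(ref.rsquared_adj)
        assert met.s == pytest.approx(np.sqrt(ref.mse_resid))
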