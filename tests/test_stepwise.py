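"""Model fitting and backward stepwise search vs independent oracles."""

import numpy as np
import pytest
import statsmodels.api as sm

from invsel.exceptions import InvalidConfigError, InvalidInputError
from invsel.stepwise import (
    INTERCEPT,
    StepwiseGLM,
    fit_glm,
    information_criterion,
    predict_scores,
    stepwise_backward,
)


def greedy_backward_oracle(X, y, family, criterion="aic"):
    """Brute-force greedy deletion using statsmodels fits at every step."""

    def fit(cols):
        D = sm.add_constant(X[:, cols]) if cols else np.ones((len(y), 1))
        if family == "logistic":
            res = sm.GLM(y, D, family=sm.families.Binomial()).fit()
            k = D.shape[1]
            ll = res.llf
        else:
            res = sm.OLS(y, D).fit()
            k = D.shape[1]
            ll = res.llf
        pen = 2.0 if criterion == "aic" else np.log(len(y))
        return -2.0 * ll + pen * k

    cols = list(range(X.shape[1]))
    current = fit(cols)
    while cols:
        cands = [(fit(cols[:i] + cols[i + 1 :]), i) for i in range(len(cols))]
        best, pos = min(cands, key=lambda t: (t[0], t[1]))
        if not best < current:
            break
        current = best
        cols = cols[:pos] + cols[pos + 1 :]
    return cols


class TestFitGLM:
    def test_intercept_only_logistic_closed_form(self):
        y = np.array([1, 0, 0, 0, 1, 0, 0, 0], dtype=float)  # mean 0.25
        model = fit_glm(np.empty((8, 0)), y, family="logistic")
        assert model.coefficients[INTERCEPT] == pytest.approx(np.log(0.25 / 0.75), abs=1e-6)

    def test_gaussian_noiseless_exact_coefficients(self):
        x = np.linspace(0, 3, 10)
        model = fit_glm(x, 1.0 + 2.0 * x, family="gaussian")
        assert model.coefficients[INTERCEPT] == pytest.approx(1.0, abs=1e-8)
        assert list(model.coefficients.values())[1] == pytest.approx(2.0, abs=1e-8)
        assert model.saturated  # zero residual sum of squares

    def test_logistic_matches_statsmodels(self):
        x = np.array([-2.0, -1.0, -0.5, 0.0, 0.2, 0.7, 1.5, 2.0])
        y = np.array([0, 0, 1, 0, 1, 0, 1, 1], dtype=float)
        model = fit_glm(x, y, family="logistic")
        ref = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        got = np.array(list(model.coefficients.values()))
        assert got == pytest.approx(ref.params, abs=1e-6)
        assert model.log_likelihood == pytest.approx(ref.llf, abs=1e-8)

    def test_gaussian_matches_statsmodels_likelihood(self, rng):
        X = rng.normal(size=(12, 3))
        y = X @ np.array([1.0, -2.0, 0.5]) + rng.normal(size=12)
        model = fit_glm(X, y, family="gaussian")
        ref = sm.OLS(y, sm.add_constant(X)).fit()
        assert model.log_likelihood == pytest.approx(ref.llf, abs=1e-8)
        assert information_criterion(model, "AIC") == pytest.approx(ref.aic, abs=1e-8)
        assert information_criterion(model, "BIC") == pytest.approx(ref.bic, abs=1e-8)

    def test_aliased_column_dropped_with_warning(self, rng):
        X = rng.normal(size=(20, 2))
        X = np.column_stack([X, X[:, 0]])  # exact duplicate
        y = X[:, 0] + rng.normal(size=20)
        with pytest.warns(UserWarning, match="aliased"):
            model = fit_glm(X, y, family="gaussian")
        assert len(model.terms) == 2

    def test_single_class_outcome_rejected(self, rng):
        with pytest.raises(InvalidInputError):
            fit_glm(rng.normal(size=(10, 2)), np.ones(10), family="logistic")


class TestInformationCriterion:
    def test_bic_minus_aic_identity(self, rng):
        X = rng.normal(size=(15, 4))
        y = rng.normal(size=15)
        model = fit_glm(X, y, family="gaussian")
        k = model.n_params
        diff = information_criterion(model, "BIC") - information_criterion(model, "AIC")
        assert diff == pytest.approx((np.log(15) - 2.0) * k, abs=1e-10)

    def test_added_regressor_costs_two_minus_likelihood_gain(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(200, 1))
        y = rng.normal(size=200)
        m0 = fit_glm(np.empty((200, 0)), y, "gaussian")
        m1 = fit_glm(X, y, "gaussian")
        gain = 2.0 * (m1.log_likelihood - m0.log_likelihood)
        delta = information_criterion(m1, "AIC") - information_criterion(m0, "AIC")
        assert delta == pytest.approx(2.0 - gain, abs=1e-10)
        assert 0.0 <= gain < 2.0  # pure noise: chi-square(1)-sized gain

    def test_unknown_kind(self, rng):
        model = fit_glm(rng.normal(size=(10, 1)), rng.normal(size=10), "gaussian")
        with pytest.raises(InvalidConfigError):
            information_criterion(model, "DIC")


class TestStepwiseBackward:
    def test_fixed_point_when_nothing_improves(self, rng):
        x = rng.normal(size=(40, 1))
        y = (x[:, 0] + rng.normal(scale=0.5, size=40) > 0).astype(float)
        model = stepwise_backward(x, y, family="logistic")
        assert model.terms == ["x0"]

    def test_noise_term_removed_strong_term_kept(self):
        rng = np.random.default_rng(4)
        strong = rng.normal(size=40)
        noise = rng.normal(size=40)
        y = 2.0 * strong + rng.normal(scale=0.5, size=40)
        model = stepwise_backward(np.column_stack([strong, noise]), y, family="gaussian")
        assert model.terms == ["x0"]

    @pytest.mark.parametrize("family", ["gaussian", "logistic"])
    @pytest.mark.parametrize("criterion", ["aic", "bic"])
    def test_matches_bruteforce_greedy_oracle(self, family, criterion):
        for seed in range(6):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(45, 6))
            eta = X[:, 0] * 1.5 - X[:, 2] + 0.5 * X[:, 4]
            if family == "logistic":
                y = (eta + rng.normal(size=45) > 0).astype(float)
            else:
                y = eta + rng.normal(size=45)
            model = stepwise_backward(X, y, family=family, criterion=criterion)
            oracle_cols = greedy_backward_oracle(X, y, family, criterion)
            assert sorted(model.term_idx.tolist()) == sorted(oracle_cols)

    def test_criterion_never_worse_than_full_model(self, rng):
        X = rng.normal(size=(50, 8))
        y = X[:, 0] + rng.normal(size=50)
        full = fit_glm(X, y, family="gaussian")
        reduced = stepwise_backward(X, y, family="gaussian")
        assert reduced.criterion_value <= information_criterion(full, "AIC") + 1e-9

    def test_cv_criterion_deterministic_for_seed(self, rng):
        X = rng.normal(size=(30, 4))
        y = (X[:, 0] + rng.normal(size=30) > 0).astype(float)
        a = stepwise_backward(X, y, family="logistic", criterion="cv", seed=5)
        b = stepwise_backward(X, y, family="logistic", criterion="cv", seed=5)
        assert a.terms == b.terms
        assert a.criterion_value == b.criterion_value


class TestPredict:
    def test_intercept_only_logistic_scores_half(self):
        y = np.array([0, 1, 0, 1], dtype=float)
        model = fit_glm(np.empty((4, 0)), y, family="logistic")
        assert predict_scores(model, np.empty((3, 0))) == pytest.approx([0.5] * 3)

    def test_gaussian_prediction_example(self):
        x = np.linspace(0, 3, 10)
        model = fit_glm(x, 1.0 + 2.0 * x, family="gaussian")
        assert predict_scores(model, np.array([[3.0]]))[0] == pytest.approx(7.0, abs=1e-8)

    def test_scores_reproduce_in_sample_fit(self, rng):
        X = rng.normal(size=(25, 3))
        y = (X[:, 0] > 0).astype(float)
        model = fit_glm(X, y, family="logistic")
        D = np.column_stack([np.ones(25), X[:, model.term_idx]])
        expected = 1.0 / (1.0 + np.exp(-np.clip(D @ model.coef_vector(), -30, 30)))
        assert predict_scores(model, X) == pytest.approx(expected, abs=1e-12)

    def test_missing_term_rejected(self, rng):
        import pandas as pd

        X = rng.normal(size=(12, 2))
        y = X[:, 0] + rng.normal(size=12)
        model = fit_glm(X, y, family="gaussian", feature_names=["a", "b"])
        with pytest.raises(InvalidInputError):
            predict_scores(model, pd.DataFrame({"a": np.arange(5.0)}))


class TestStepwiseGLMEstimator:
    def test_estimator_roundtrip(self, rng):
        from sklearn.base import clone

        X = rng.normal(size=(40, 5))
        y = (X[:, 1] + rng.normal(scale=0.5, size=40) > 0).astype(float)
        est = StepwiseGLM(criterion="aic", random_state=0)
        assert clone(est).get_params()["criterion"] == "aic"
        est.fit(X, y)
        assert 1 in est.terms_
        proba = est.predict_proba(X)
        assert proba.shape == (40, 2)
        assert np.allclose(proba.sum(axis=1), 1.0)
        assert set(np.unique(est.predict(X))) <= {0, 1}

    def test_gaussian_predict_returns_scores(self, rng):
        X = rng.normal(size=(30, 3))
        y = X[:, 0] * 2.0 + rng.normal(size=30)
        est = StepwiseGLM(family="gaussian").fit(X, y)
        assert np.allclose(est.predict(X), est.predict_scores(X))
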