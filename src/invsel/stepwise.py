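"""Final model training: GLM fit plus backward stepwise reduction.

The candidate features surviving a pre-filter are combined into one model —
logistic regression for a binary classification, a linear model for
semi-quantitative (equidistant integer) ratings — which is then reduced by
backward stepwise selection: at each round every single-term deletion is
scored by the chosen criterion (AIC by default, BIC, or k-fold CV error) and
the best deletion is accepted while it strictly improves on the current
model.  The intercept is never removed.

Numerical conventions
---------------------
* The Gaussian log-likelihood is the profile form at the variance MLE,
  -n/2*(log(2*pi*RSS/n)+1), so AIC/BIC differences match the standard
  stepwise convention; the parameter count k is the number of mean
  parameters (intercept included, error variance not counted).
* A model whose parameter count reaches the sample count fits the data
  exactly; its effective parameter count is capped at n (the attainable
  rank for generic continuous features).  A Gaussian fit with numerically
  zero residual is treated as saturated: its criterion is -infinity and no
  deletion can improve it, so the stepwise search stops there.
* Logistic fits use Newton/IRLS with clamped linear predictors, so complete
  separation yields a converged fit with bounded coefficients rather than a
  crash; whether a fit "converged" is reported and used by the benchmark's
  definition of a successful model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from ._glm import gaussian_llf, kfold_indices, logistic_fit, ols_fit, sigmoid
from .exceptions import InvalidConfigError, InvalidInputError

__all__ = [
    "FittedModel",
    "fit_glm",
    "information_criterion",
    "stepwise_backward",
    "predict_scores",
    "StepwiseGLM",
]

INTERCEPT = "(Intercept)"


@dataclass
class FittedModel:
    """A fitted (generalised) linear model on a set of retained terms."""

    family: str  # "logistic" | "gaussian"
    terms: list[str]  # retained feature names, intercept excluded
    term_idx: np.ndarray  # column indices of the terms in the training X
    coefficients: dict[str, float]  # includes "(Intercept)"
    log_likelihood: float
    criterion_kind: str
    criterion_value: float
    converged: bool
    n_obs: int
    saturated: bool = False
    scale: float = field(default=np.nan)  # gaussian residual variance (MLE)

    @property
    def n_params(self) -> int:
        """Effective number of mean parameters (capped at n_obs)."""
        return min(len(self.terms) + 1, self.n_obs)

    def coef_vector(self) -> np.ndarray:
        return np.array([self.coefficients[INTERCEPT]] + [self.coefficients[t] for t in self.terms])


def _default_names(p: int) -> list[str]:
    width = len(str(max(p - 1, 1)))
    return [f"x{j:0{width}d}" for j in range(p)]


def _rss_tol(y: np.ndarray) -> float:
    return 1e-12 * (float(y @ y) + 1.0)


def _fit_design(D: np.ndarray, y: np.ndarray, family: str, start=None, max_iter=25):
    """Fit on an explicit design (intercept already included).

    Returns (coef, llf, converged, saturated, scale).
    """
    n = D.shape[0]
    if family == "gaussian":
        coef, rss, _ = ols_fit(D, y)
        tol = _rss_tol(y)
        saturated = rss <= tol
        llf = float(gaussian_llf(max(rss, tol), n))
        return coef, llf, True, saturated, max(rss, 0.0) / n
    coef, llf, converged, _ = logistic_fit(D, y, start=start, max_iter=max_iter)
    return coef, llf, converged, False, np.nan


def information_criterion(model: FittedModel, kind: str = "AIC", n: int | None = None) -> float:
    """AIC = -2*llf + 2k or BIC = -2*llf + log(n)*k for a fitted model."""
    kind = kind.upper()
    n = model.n_obs if n is None else n
    if model.saturated:
        return -np.inf
    k = model.n_params
    if kind == "AIC":
        return -2.0 * model.log_likelihood + 2.0 * k
    if kind == "BIC":
        return -2.0 * model.log_likelihood + np.log(n) * k
    raise InvalidConfigError(f"unknown information criterion: {kind!r}")


def _drop_aliased(X: np.ndarray) -> np.ndarray:
    """Indices of a maximal linearly independent subset of [1, X] columns."""
    n, p = X.shape
    D = np.column_stack([np.ones(n), X])
    _, _, piv = linalg.qr(D, mode="economic", pivoting=True)
    r = np.linalg.matrix_rank(D)
    keep = np.sort(piv[:r])
    keep_feat = keep[keep > 0] - 1
    if keep_feat.size < p:
        warnings.warn(f"dropping {p - keep_feat.size} aliased column(s)")
    return keep_feat


def fit_glm(
    X,
    y,
    family: str = "auto",
    feature_names: list[str] | None = None,
    criterion_kind: str = "AIC",
) -> FittedModel:
    """Maximum-likelihood fit of y ~ X for the requested family.

    ``family="auto"`` picks logistic for 0/1 labels and gaussian otherwise.
    Rank-deficient designs have their aliased columns dropped with a warning;
    a single-class binary outcome is rejected.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if family == "auto":
        family = "logistic" if np.isin(y, (0, 1)).all() else "gaussian"
    if family not in ("logistic", "gaussian"):
        raise InvalidConfigError(f"unknown family: {family!r}")
    if family == "logistic":
        if not np.isin(y, (0, 1)).all():
            raise InvalidInputError("logistic family requires 0/1 outcomes")
        if y.min() == y.max():
            raise InvalidInputError("single-class outcome: cannot fit a logistic model")
    names = list(feature_names) if feature_names is not None else _default_names(p)
    if len(names) != p:
        raise InvalidInputError("feature_names length does not match X")
    keep = _drop_aliased(X) if p and min(n, p) > 0 else np.arange(p)
    D = np.column_stack([np.ones(n), X[:, keep]])
    coef, llf, converged, saturated, scale = _fit_design(D, y, family)
    terms = [names[j] for j in keep]
    model = FittedModel(
        family=family,
        terms=terms,
        term_idx=np.asarray(keep, dtype=int),
        coefficients={INTERCEPT: float(coef[0]), **{t: float(c) for t, c in zip(terms, coef[1:])}},
        log_likelihood=float(llf),
        criterion_kind=criterion_kind.upper() if criterion_kind.upper() in ("AIC", "BIC") else "AIC",
        criterion_value=np.nan,
        converged=bool(converged),
        n_obs=n,
        saturated=bool(saturated),
        scale=scale,
    )
    model.criterion_value = information_criterion(model, model.criterion_kind)
    return model


def _cv_error(D: np.ndarray, y: np.ndarray, family: str, folds) -> float:
    """k-fold CV error (misclassification rate / MSE) of a design."""
    n = D.shape[0]
    err = 0.0
    for test_idx in folds:
        train = np.ones(n, dtype=bool)
        train[test_idx] = False
        coef, _, _, _, _ = _fit_design(D[train], y[train], family)
        eta = D[test_idx] @ coef
        if family == "logistic":
            err += float(np.sum((sigmoid(eta) > 0.5).astype(int) != y[test_idx]))
        else:
            err += float(np.sum((eta - y[test_idx]) ** 2))
    return err / n


def stepwise_backward(
    X,
    y,
    family: str = "auto",
    criterion: str = "AIC",
    k_folds: int = 5,
    seed: int | None = None,
    feature_names: list[str] | None = None,
    initial: FittedModel | None = None,
) -> FittedModel:
    """Backward stepwise reduction of the full model y ~ X.

    Every round scores each single-term deletion by the criterion (AIC, BIC,
    or k-fold CV error with folds drawn once per round so candidate
    comparisons are paired) and accepts the best deletion if it is strictly
    better than the current model; otherwise the search stops.  Ties go to
    the earliest term.  Deterministic for a fixed seed.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    crit = criterion.upper()
    if crit not in ("AIC", "BIC", "CV"):
        raise InvalidConfigError(f"unknown criterion: {criterion!r}")
    if initial is None:
        initial = fit_glm(X, y, family=family, feature_names=feature_names,
                          criterion_kind=crit if crit != "CV" else "AIC")
    family = initial.family
    n = X.shape[0]
    rng = np.random.default_rng(seed)

    current_idx = list(initial.term_idx)
    names = {j: t for j, t in zip(initial.term_idx, initial.terms)}
    D_full = np.column_stack([np.ones(n), X])

    def make_design(idx):
        return D_full[:, [0] + [j + 1 for j in idx]]

    cur_coef = initial.coef_vector()
    cur_llf = initial.log_likelihood
    cur_sat = initial.saturated
    cur_conv = initial.converged
    cur_scale = initial.scale

    def ic_value(llf, saturated, n_terms):
        if saturated:
            return -np.inf
        k = min(n_terms + 1, n)
        pen = 2.0 if crit == "AIC" else np.log(n)
        return -2.0 * llf + pen * k

    if crit == "CV":
        folds = kfold_indices(n, min(k_folds, n), rng)
        cur_crit = _cv_error(make_design(current_idx), y, family, folds)
    else:
        cur_crit = ic_value(cur_llf, cur_sat, len(current_idx))

    while current_idx:
        if crit == "CV":
            folds = kfold_indices(n, min(k_folds, n), rng)
            cur_crit = _cv_error(make_design(current_idx), y, family, folds)
        best = None
        for pos in range(len(current_idx)):
            cand_idx = current_idx[:pos] + current_idx[pos + 1 :]
            D = make_design(cand_idx)
            if crit == "CV":
                cand_crit = _cv_error(D, y, family, folds)
                cand_fit = None
            else:
                # candidates are refit from scratch: warm starts inherited
                # from a near-separated parent stall IRLS in a flat region.
                # a reduced iteration cap suffices to rank candidates; the
                # accepted deletion is refit fully below
                cand_fit = _fit_design(D, y, family, max_iter=10)
                cand_crit = ic_value(cand_fit[1], cand_fit[3], len(cand_idx))
            if best is None or cand_crit < best[0]:
                best = (cand_crit, pos, cand_fit)
        if best is None or not best[0] < cur_crit:
            break
        cur_crit, pos, cand_fit = best
        current_idx = current_idx[:pos] + current_idx[pos + 1 :]
        # full refit of the accepted model (candidate evaluation is capped)
        cand_fit = _fit_design(make_design(current_idx), y, family)
        cur_coef, cur_llf, cur_conv, cur_sat, cur_scale = cand_fit
        if crit != "CV":
            cur_crit = ic_value(cur_llf, cur_sat, len(current_idx))

    terms = [names[j] for j in current_idx]
    final_crit = (
        cur_crit if crit == "CV" else ic_value(cur_llf, cur_sat, len(current_idx))
    )
    return FittedModel(
        family=family,
        terms=terms,
        term_idx=np.asarray(current_idx, dtype=int),
        coefficients={
            INTERCEPT: float(cur_coef[0]),
            **{t: float(c) for t, c in zip(terms, cur_coef[1:])},
        },
        log_likelihood=float(cur_llf),
        criterion_kind=crit,
        criterion_value=float(final_crit),
        converged=bool(cur_conv),
        n_obs=n,
        saturated=bool(cur_sat),
        scale=cur_scale,
    )


def predict_scores(model: FittedModel, X) -> np.ndarray:
    """Per-sample model scores: probabilities (logistic) or fitted values.

    ``X`` is the feature matrix in the training column layout, or a
    DataFrame containing every model term as a column.
    """
    if isinstance(X, pd.DataFrame):
        missing = [t for t in model.terms if t not in X.columns]
        if missing:
            raise InvalidInputError(f"missing model terms in X: {missing}")
        F = X[model.terms].to_numpy(dtype=float) if model.terms else np.empty((len(X), 0))
    else:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if model.term_idx.size and X.shape[1] <= model.term_idx.max():
            raise InvalidInputError("X has fewer columns than the training feature space")
        F = X[:, model.term_idx]
    eta = model.coefficients[INTERCEPT] + (
        F @ np.array([model.coefficients[t] for t in model.terms]) if model.terms else 0.0
    )
    eta = np.asarray(eta, dtype=float) + np.zeros(F.shape[0])
    return sigmoid(eta) if model.family == "logistic" else eta


class StepwiseGLM(BaseEstimator):
    """Backward-stepwise GLM in scikit-learn estimator form.

    Fits a full logistic (binary y) or Gaussian (numeric y) model on all
    input columns and reduces it by backward stepwise selection under the
    chosen criterion.

    Parameters
    ----------
    family : {"auto", "logistic", "gaussian"}
    criterion : {"aic", "bic", "cv"}
    cv : int, default 5 — folds of the CV criterion
    random_state : int or None — seed of the CV criterion folds

    Attributes
    ----------
    model_ : FittedModel
    terms_ : list of retained column indices into the input X
    coef_, intercept_ : retained-term coefficients
    llf_, criterion_value_, converged_ : fit summaries
    """

    def __init__(self, family="auto", criterion="aic", cv=5, random_state=None):
        self.family = family
        self.criterion = criterion
        self.cv = cv
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        self.n_features_in_ = X.shape[1]
        self.model_ = stepwise_backward(
            X,
            y,
            family=self.family,
            criterion=self.criterion,
            k_folds=self.cv,
            seed=self.random_state,
        )
        self.terms_ = list(self.model_.term_idx)
        self.coef_ = np.array([self.model_.coefficients[t] for t in self.model_.terms])
        self.intercept_ = self.model_.coefficients[INTERCEPT]
        self.llf_ = self.model_.log_likelihood
        self.criterion_value_ = self.model_.criterion_value
        self.converged_ = self.model_.converged
        if self.model_.family == "logistic":
            self.classes_ = np.array([0, 1])
        return self

    def predict_scores(self, X):
        check_is_fitted(self, "model_")
        X = check_array(X, dtype=float)
        return predict_scores(self.model_, X)

    def predict(self, X):
        scores = self.predict_scores(X)
        if self.model_.family == "logistic":
            return (scores > 0.5).astype(int)
        return scores

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        if self.model_.family != "logistic":
            raise InvalidInputError("predict_proba is only defined for the logistic family")
        p = self.predict_scores(X)
        return np.column_stack([1.0 - p, p])
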