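"""Standard cross-validation feature ranking (the V2 baseline).

Each feature is scored by how well a univariate model predicts the observed
classification from it: k-fold CV accuracy of a logistic model for binary
labels, k-fold CV mean squared error of a linear model for semi-quantitative
labels.  The top ``n`` features (highest accuracy or lowest error) are kept,
with ``n`` conventionally the number of samples.

Unlike the inverted-role screen this ranking always returns a candidate set
of size min(n_features, n): it has no notion of "no informative features",
which is exactly the failure mode the inverted-role screen is designed to
expose.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from ._glm import kfold_indices, logistic_batch_1d, ols_batch_1d, sigmoid
from .exceptions import InvalidConfigError, InvalidInputError

__all__ = [
    "cv_standard_binary",
    "cv_standard_linear",
    "select_top_v2",
    "CVRankSelector",
]

_PROB_EPS = 1e-10


def _check_folds(n: int, k: int) -> int:
    if not 2 <= k <= n:
        raise InvalidConfigError("k_folds must lie in [2, n_samples]")
    return k


def _cv_binary_batch(F: np.ndarray, y: np.ndarray, k_folds: int, seed) -> np.ndarray:
    """Held-out classification accuracy of y ~ feature, per column of F."""
    n = F.shape[0]
    rng = np.random.default_rng(seed)
    folds = kfold_indices(n, _check_folds(n, k_folds), rng)
    correct = np.zeros(F.shape[1])
    for test_idx in folds:
        train = np.ones(n, dtype=bool)
        train[test_idx] = False
        a, b = logistic_batch_1d(F[train], y[train])
        prob = sigmoid(a[None, :] + F[test_idx] * b[None, :])
        prob = np.clip(prob, _PROB_EPS, 1.0 - _PROB_EPS)
        pred = (prob > 0.5).astype(int)
        correct += (pred == y[test_idx, None]).sum(axis=0)
    return correct / n


def _cv_linear_batch(F: np.ndarray, y: np.ndarray, k_folds: int, seed) -> np.ndarray:
    """Held-out MSE of y ~ feature, per column of F."""
    n = F.shape[0]
    rng = np.random.default_rng(seed)
    folds = kfold_indices(n, _check_folds(n, k_folds), rng)
    sq_err = np.zeros(F.shape[1])
    for test_idx in folds:
        train = np.ones(n, dtype=bool)
        train[test_idx] = False
        a, b = ols_batch_1d(F[train], y[train])
        pred = a[None, :] + F[test_idx] * b[None, :]
        sq_err += ((pred - y[test_idx, None]) ** 2).sum(axis=0)
    return sq_err / n


def cv_standard_binary(feature, classification, k_folds: int = 10, seed=None) -> float:
    """CV accuracy of the univariate logistic model classification ~ feature.

    Held-out probabilities are thresholded at 0.5; under separation inside a
    fold the probabilities are clamped away from {0, 1} so the accuracy stays
    defined.  Default fold count follows the convention of the classical
    binary-CV helper this mirrors.
    """
    y = np.asarray(classification)
    if not np.isin(y, (0, 1)).all():
        raise InvalidInputError("binary CV requires 0/1 labels")
    if y.min() == y.max():
        raise InvalidInputError("both classes must be present")
    F = np.asarray(feature, dtype=float)[:, None]
    return float(_cv_binary_batch(F, y.astype(int), k_folds, seed)[0])


def cv_standard_linear(feature, classification, k_folds: int = 3, seed=None) -> float:
    """CV mean squared error of the linear model classification ~ feature."""
    F = np.asarray(feature, dtype=float)[:, None]
    y = np.asarray(classification, dtype=float)
    return float(_cv_linear_batch(F, y, k_folds, seed)[0])


def select_top_v2(scores, n: int, direction: str = "lower-better") -> np.ndarray:
    """Top-``n`` feature indices by CV score, stable tie-break by index."""
    scores = np.asarray(scores, dtype=float)
    if n < 1:
        raise InvalidConfigError("n must be >= 1")
    key = scores if direction == "lower-better" else -scores
    if direction not in ("lower-better", "higher-better"):
        raise InvalidConfigError(f"unknown direction: {direction!r}")
    order = np.argsort(key, kind="stable")
    return order[: min(n, scores.size)]


class CVRankSelector(SelectorMixin, BaseEstimator):
    """Feature selector ranking features by univariate CV prediction of y.

    Parameters
    ----------
    model : {"auto", "logistic", "linear"}, default "auto"
        Univariate model family; "auto" picks logistic for 0/1 labels and
        linear otherwise.
    cv : int or None
        Fold count; None uses the family default (10 for logistic, 3 for
        linear).
    n_select : int or None
        Number of features kept; None means the number of samples.
    random_state : int or None
        Seed of the fold assignment.

    Attributes
    ----------
    score_ : ndarray — per-feature CV accuracy (logistic) or MSE (linear)
    direction_ : str — "higher-better" or "lower-better"
    selected_idx_ : ndarray — kept features, best first
    """

    def __init__(self, model="auto", cv=None, n_select=None, random_state=None):
        self.model = model
        self.cv = cv
        self.n_select = n_select
        self.random_state = random_state

    def _resolve_family(self, y) -> str:
        if self.model in ("logistic", "linear"):
            return self.model
        if self.model != "auto":
            raise InvalidConfigError(f"unknown model: {self.model!r}")
        return "logistic" if np.isin(y, (0, 1)).all() else "linear"

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        self.n_features_in_ = X.shape[1]
        family = self._resolve_family(y)
        n = X.shape[0]
        if family == "logistic":
            yb = y.astype(int)
            if yb.min() == yb.max():
                raise InvalidInputError("both classes must be present")
            k = min(self.cv or 10, n)
            self.score_ = _cv_binary_batch(X, yb, k, self.random_state)
            self.direction_ = "higher-better"
        else:
            k = min(self.cv or 3, n)
            self.score_ = _cv_linear_batch(X, y, k, self.random_state)
            self.direction_ = "lower-better"
        self.family_ = family
        n_keep = self.n_select if self.n_select is not None else n
        self.selected_idx_ = select_top_v2(self.score_, n_keep, self.direction_)
        self.n_selected_ = int(self.selected_idx_.size)
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "selected_idx_")
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.selected_idx_] = True
        return mask

    def transform(self, X):
        check_is_fitted(self, "selected_idx_")
        X = check_array(X, dtype=float)
        return X[:, self._get_support_mask()]
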