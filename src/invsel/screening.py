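"""Inverted-role feature pre-filtering (the V1 heuristic).

The screen treats each feature as the *dependent* variable and the (possibly
erroneous) classification as the predictor: a per-feature Gaussian linear
model likelihood-ratio test against the intercept-only null, multiplicity
adjustment, a strict cut at the significance level, then k-fold
cross-validation — still in inverted roles — to order the surviving features
by prediction error.  The final candidate list is the lowest-error features,
capped at min(number surviving, number of samples).

The rationale: when the classification contains errors, a model forced to
predict the classification rewards features that track the errors; testing
whether the classification explains each feature, with family-wise or FDR
control, instead retains features with a real association and can return an
empty set when the labels carry no information — itself an informative
outcome.

The classification enters as a single numeric regressor (one degree of
freedom) for both binary 0/1 and semi-quantitative labels, reflecting the
equidistant-category assumption of the rating scales this targets.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y
from statsmodels.stats.multitest import multipletests

from ._glm import kfold_indices
from .exceptions import (
    DegenerateDesignError,
    InvalidConfigError,
    InvalidInputError,
    UndefinedCVError,
)

__all__ = [
    "lrt_pvalue",
    "lrt_pvalues",
    "adjust_pvalues",
    "filter_significant",
    "cv_inverted",
    "select_top_v1",
    "InvertedRoleSelector",
]

_ADJUST_METHODS = {
    "BH": "fdr_bh",
    "bonferroni": "bonferroni",
    "holm": "holm",
    "none": None,
}


def _designs(
    classification: np.ndarray,
    covariates: np.ndarray | None,
    encoding: str = "numeric",
):
    """Null and full design matrices for the inverted-role linear model.

    Covariates enter both designs, so the LRT isolates the classification
    term.  With the default numeric encoding the classification contributes
    one added degree of freedom (equidistant-category assumption); the
    optional ``"factor"`` encoding adds one indicator per non-reference
    level instead.
    """
    y = np.asarray(classification, dtype=float)
    n = y.size
    if np.ptp(y) == 0:
        raise DegenerateDesignError("classification is constant")
    cols_null = [np.ones(n)]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        if cov.shape[0] != n:
            raise InvalidInputError("covariates do not match the sample count")
        cols_null.append(cov)
    D0 = np.column_stack(cols_null)
    if encoding == "numeric":
        added = y[:, None]
    elif encoding == "factor":
        levels = np.unique(y)
        added = (y[:, None] == levels[None, 1:]).astype(float)
    else:
        raise InvalidConfigError(f"unknown classification encoding: {encoding!r}")
    D1 = np.column_stack([D0, added])
    return D0, D1


def _rss_columns(D: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Residual sum of squares of each column of X regressed on design D."""
    beta, _, _, _ = np.linalg.lstsq(D, X, rcond=None)
    R = X - D @ beta
    return np.einsum("ij,ij->j", R, R)


def lrt_pvalues(
    X: np.ndarray,
    classification: np.ndarray,
    covariates: np.ndarray | None = None,
    encoding: str = "numeric",
) -> np.ndarray:
    """Per-feature LRT p-values for feature ~ classification (+ covariates).

    The test statistic is n*log(RSS_null/RSS_full), the Gaussian
    likelihood-ratio against chi-square with as many degrees of freedom as
    the classification adds to the design (1 for the default numeric
    encoding).  Features with (conditionally) zero variance get p = 1 so a
    dead probe can never be selected; a perfectly explained feature (zero
    full-model residual) gets p = 0.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    D0, D1 = _designs(classification, covariates, encoding)
    df = D1.shape[1] - D0.shape[1]
    rss0 = _rss_columns(D0, X)
    rss1 = _rss_columns(D1, X)
    scale = np.einsum("ij,ij->j", X, X) + 1.0
    tol = 1e-12 * scale
    p = np.ones(X.shape[1])
    dead = rss0 <= tol
    perfect = (~dead) & (rss1 <= tol)
    ok = ~dead & ~perfect
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = n * np.log(rss0[ok] / rss1[ok])
    p[ok] = stats.chi2.sf(np.maximum(stat, 0.0), df=df)
    p[perfect] = 0.0
    return p


def lrt_pvalue(feature, classification, covariates=None, encoding="numeric") -> float:
    """LRT p-value for a single feature; see :func:`lrt_pvalues`."""
    return float(
        lrt_pvalues(
            np.asarray(feature, dtype=float), classification, covariates, encoding
        )[0]
    )


def adjust_pvalues(p, method: str = "BH") -> np.ndarray:
    """Multiplicity adjustment (Benjamini-Hochberg, Bonferroni, Holm or none).

    Preserves input order; adjusted values are capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise InvalidInputError("p-values must lie in [0, 1]")
    if method not in _ADJUST_METHODS:
        raise InvalidConfigError(f"unknown adjustment method: {method!r}")
    if method == "none" or p.size == 0:
        return p.copy()
    return multipletests(p, method=_ADJUST_METHODS[method])[1]


def filter_significant(adjusted_p, alpha: float = 0.05) -> np.ndarray:
    """Indices with adjusted p strictly below ``alpha``."""
    if not 0.0 < alpha < 1.0:
        raise InvalidConfigError("alpha must lie in (0, 1)")
    return np.flatnonzero(np.asarray(adjusted_p, dtype=float) < alpha)


def _cv_inverted_batch(
    X: np.ndarray,
    classification: np.ndarray,
    covariates: np.ndarray | None,
    k_folds: int,
    seed: int | None,
    encoding: str = "numeric",
) -> np.ndarray:
    """Inverted-role k-fold CV error for every column of X at once.

    All features share the same (classification + covariate) design, so each
    fold needs a single least-squares solve for the whole matrix.  Folds in
    which the training classification is constant are skipped with a warning.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not 2 <= k_folds <= n:
        raise InvalidConfigError("k_folds must lie in [2, n_samples]")
    D0, D1 = _designs(classification, covariates, encoding)
    rng = np.random.default_rng(seed)
    folds = kfold_indices(n, k_folds, rng)
    sq_err = np.zeros(X.shape[1])
    n_held_out = 0
    for test_idx in folds:
        train = np.ones(n, dtype=bool)
        train[test_idx] = False
        if np.ptp(np.asarray(classification, dtype=float)[train]) == 0:
            warnings.warn("fold skipped: constant classification in training set")
            continue
        beta, _, _, _ = np.linalg.lstsq(D1[train], X[train], rcond=None)
        resid = X[test_idx] - D1[test_idx] @ beta
        sq_err += np.einsum("ij,ij->j", resid, resid)
        n_held_out += test_idx.size
    if n_held_out == 0:
        raise UndefinedCVError("every fold had a constant training classification")
    return sq_err / n_held_out


def cv_inverted(
    feature,
    classification,
    covariates=None,
    k_folds: int = 3,
    seed: int | None = None,
) -> float:
    """Mean squared k-fold CV error of the model feature ~ classification."""
    err = _cv_inverted_batch(
        np.asarray(feature, dtype=float)[:, None], classification, covariates, k_folds, seed
    )
    return float(err[0])


def select_top_v1(cv_errors, n_samples: int, feature_idx=None) -> np.ndarray:
    """Order features by CV error and cap at min(count, n_samples).

    ``cv_errors`` refer to the features in ``feature_idx`` (defaults to
    0..len-1); ties keep the original feature order (stable sort), so runs
    are reproducible.
    """
    cv_errors = np.asarray(cv_errors, dtype=float)
    if feature_idx is None:
        feature_idx = np.arange(cv_errors.size)
    feature_idx = np.asarray(feature_idx)
    order = np.argsort(cv_errors, kind="stable")
    return feature_idx[order][: min(cv_errors.size, int(n_samples))]


class InvertedRoleSelector(SelectorMixin, BaseEstimator):
    """Feature selector screening with inverted dependent/independent roles.

    Per feature: Gaussian LRT of feature ~ label against feature ~ 1,
    multiplicity adjustment, strict cut at ``alpha``, then seeded k-fold
    cross-validation of the same inverted-role model to rank the survivors;
    the lowest-error features are kept, at most one per sample.

    Parameters
    ----------
    alpha : float, default 0.05
        Significance level applied to adjusted p-values (strict ``<``).
    adjust : {"BH", "bonferroni", "holm", "none"}, default "BH"
        Multiplicity adjustment.
    cv : int, default 3
        Number of cross-validation folds for the ranking step.
    encoding : {"numeric", "factor"}, default "numeric"
        How the classification enters the inverted-role designs: as a single
        equidistant numeric regressor (default) or as category indicators.
    random_state : int or None
        Seed of the fold assignment.

    Attributes
    ----------
    raw_p_, adjusted_p_ : ndarray of shape (n_features,)
    significant_idx_ : ndarray — indices passing the adjusted-p cut
    cv_error_ : ndarray of shape (n_features,) — NaN for non-significant features
    selected_idx_ : ndarray — final candidates ordered by increasing CV error
    n_selected_ : int

    The selector may legitimately select nothing; ``transform`` then returns
    a (n_samples, 0) matrix and downstream model building should treat the
    condition as "no model".
    """

    def __init__(self, alpha=0.05, adjust="BH", cv=3, encoding="numeric",
                 random_state=None):
        self.alpha = alpha
        self.adjust = adjust
        self.cv = cv
        self.encoding = encoding
        self.random_state = random_state

    def fit(self, X, y, covariates=None):
        X, y = check_X_y(X, y, dtype=float)
        self.n_features_in_ = X.shape[1]
        self.raw_p_ = lrt_pvalues(X, y, covariates, self.encoding)
        self.adjusted_p_ = adjust_pvalues(self.raw_p_, self.adjust)
        self.significant_idx_ = filter_significant(self.adjusted_p_, self.alpha)
        self.cv_error_ = np.full(X.shape[1], np.nan)
        if self.significant_idx_.size:
            errs = _cv_inverted_batch(
                X[:, self.significant_idx_],
                y,
                covariates,
                min(self.cv, X.shape[0]),
                self.random_state,
                self.encoding,
            )
            self.cv_error_[self.significant_idx_] = errs
            self.selected_idx_ = select_top_v1(errs, X.shape[0], self.significant_idx_)
        else:
            self.selected_idx_ = np.array([], dtype=int)
        self.n_selected_ = int(self.selected_idx_.size)
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "selected_idx_")
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.selected_idx_] = True
        return mask

    def transform(self, X):
        # bypass sklearn's empty-selection guard: an empty candidate set is a
        # meaningful outcome here, not an error
        check_is_fitted(self, "selected_idx_")
        X = check_array(X, dtype=float)
        return X[:, self._get_support_mask()]
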