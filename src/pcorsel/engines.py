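"""Regression engines for neighbor-restricted fits.

Each engine maps a centered response and a centered covariate matrix to a
coefficient vector. Ordinary least squares is the exact-method choice when
the neighborhood is small relative to n; the regularized engines (ridge with
K-fold CV, ridge with the analytic Hoerl–Kennard–Baldwin penalty, PLS, lasso,
adaptive lasso) cover high-dimensional neighborhoods.

Ridge cross-validation is computed from one SVD per fold, from which the
whole penalty grid is evaluated at negligible extra cost; this keeps the
per-node cost low enough to run the iterative graph-inference experiments in
reasonable time. Lasso, adaptive lasso and PLS delegate to scikit-learn.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.linear_model import LassoCV
from sklearn.model_selection import KFold

ENGINE_NAMES = ("ols", "ridge_cv", "ridge_analytic", "pls", "lasso", "adalasso")

#: floor for the analytic ridge penalty when the least-squares fit is perfect
LAMBDA_MIN = 1e-8


def analytic_ridge_parameter(response: np.ndarray, covariates: np.ndarray, lambda_min: float = LAMBDA_MIN) -> float:
    """Hoerl–Kennard–Baldwin plug-in ridge penalty λ = q·s²/‖β̂‖².

    β̂ is the least-squares solution (minimum-norm when the design is
    rank-deficient), s² the residual variance RSS/(n − rank), and q the number
    of covariates. Returns ``lambda_min`` when the fit is perfect.
    """
    y = np.asarray(response, dtype=float).ravel()
    X = np.asarray(covariates, dtype=float)
    n, q = X.shape
    if q < 2:
        raise ValueError("analytic ridge parameter requires at least 2 covariates")
    if n < 3:
        raise ValueError("analytic ridge parameter requires at least 3 observations")
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta) ** 2))
    dof = max(n - rank, 1)
    s2 = rss / dof
    norm2 = float(beta @ beta)
    if s2 <= lambda_min * norm2 or norm2 == 0.0:
        return lambda_min
    lam = q * s2 / norm2
    return max(lam, lambda_min)


def _ridge_solve(X: np.ndarray, y: np.ndarray, alpha: float) -> np.ndarray:
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    d = s / (s**2 + alpha)
    return Vt.T @ (d * (U.T @ y))


def _ridge_cv_path(X: np.ndarray, y: np.ndarray, alphas: np.ndarray, folds: int, seed: int) -> tuple[np.ndarray, float]:
    """K-fold CV over a ridge penalty grid; returns (coefficients, best alpha)."""
    n = X.shape[0]
    k = min(folds, n)
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    sse = np.zeros(len(alphas))
    for train, test in kf.split(X):
        U, s, Vt = np.linalg.svd(X[train], full_matrices=False)
        Uty = U.T @ y[train]
        for a, alpha in enumerate(alphas):
            beta = Vt.T @ ((s / (s**2 + alpha)) * Uty)
            resid = y[test] - X[test] @ beta
            sse[a] += float(resid @ resid)
    best = float(alphas[int(np.argmin(sse))])
    return _ridge_solve(X, y, best), best


def _pls_cv(X: np.ndarray, y: np.ndarray, max_components: int, folds: int, seed: int) -> tuple[np.ndarray, int]:
    n, q = X.shape
    k = min(folds, n)
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    splits = list(kf.split(X))
    min_train = min(len(tr) for tr, _ in splits)
    cmax = max(1, min(q, min_train - 1, max_components))
    sse = np.zeros(cmax)
    for train, test in splits:
        for c in range(1, cmax + 1):
            pls = PLSRegression(n_components=c, scale=False)
            pls.fit(X[train], y[train])
            resid = y[test] - pls.predict(X[test]).ravel()
            sse[c - 1] += float(resid @ resid)
    best = int(np.argmin(sse)) + 1
    pls = PLSRegression(n_components=best, scale=False)
    pls.fit(X, y)
    return np.asarray(pls.coef_).reshape(-1), best


def _lasso_fit(X: np.ndarray, y: np.ndarray, folds: int, seed: int) -> tuple[np.ndarray, float]:
    """LassoCV with seeded K-fold splits; no internal rescaling."""
    k = min(folds, X.shape[0])
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    model = LassoCV(cv=kf, max_iter=10000)
    model.fit(X, y)
    return model.coef_, float(model.alpha_)


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sd = X.std(axis=0, ddof=0)
    if np.any(sd == 0):
        raise ValueError("lasso engines require non-constant covariate columns")
    return X / sd, sd


@dataclass
class RegressionEngine:
    """A named fitting strategy mapping (response, covariates) to coefficients.

    ``seed`` controls CV fold assignment; fits are deterministic given it.
    """

    name: str = "ols"
    cv_folds: int = 10
    seed: int = 0
    ridge_alphas: np.ndarray = field(default_factory=lambda: np.logspace(-4, 4, 25))
    max_pls_components: int = 15
    lambda_min: float = LAMBDA_MIN

    def __post_init__(self) -> None:
        if self.name not in ENGINE_NAMES:
            raise ValueError(f"unknown engine {self.name!r}; expected one of {ENGINE_NAMES}")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if len(self.ridge_alphas) == 0:
            raise ValueError("ridge penalty grid must be nonempty")

    def fit(self, y: np.ndarray, X: np.ndarray, seed: int | None = None) -> tuple[np.ndarray, float | int | None]:
        """Fit centered response ``y`` on centered covariates ``X``.

        Returns (coefficients, selected hyperparameter). The hyperparameter is
        the ridge penalty, lasso alpha or PLS component count; None for OLS.
        """
        y = np.asarray(y, dtype=float).ravel()
        X = np.asarray(X, dtype=float)
        n, q = X.shape
        if q == 0:
            return np.zeros(0), None
        seed = self.seed if seed is None else int(seed)

        if self.name == "ols":
            if q >= n - 1:
                raise ValueError(
                    f"OLS requires fewer neighbors ({q}) than n-1 ({n - 1}); use a regularized engine"
                )
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            return beta, None
        if self.name == "ridge_cv":
            return _ridge_cv_path(X, y, np.asarray(self.ridge_alphas, dtype=float), self.cv_folds, seed)
        if self.name == "ridge_analytic":
            if q == 1:
                # HKB needs >= 2 covariates; a single neighbor is a plain simple regression
                beta, *_ = np.linalg.lstsq(X, y, rcond=None)
                return beta, None
            lam = analytic_ridge_parameter(y, X, self.lambda_min)
            return _ridge_solve(X, y, lam), lam
        if self.name == "pls":
            return _pls_cv(X, y, self.max_pls_components, self.cv_folds, seed)
        if self.name == "lasso":
            # columns standardized so the penalty treats covariates comparably
            Xs, sd = _standardize(X)
            coef, alpha = _lasso_fit(Xs, y, self.cv_folds, seed)
            return coef / sd, alpha
        if self.name == "adalasso":
            Xs, sd = _standardize(X)
            init, _ = _ridge_cv_path(Xs, y, np.asarray(self.ridge_alphas, dtype=float), self.cv_folds, seed)
            keep = np.abs(init) > 1e-12
            beta = np.zeros(q)
            if keep.sum() == 0:
                return beta, None
            # Zou weights 1/|β̂_init| (γ=1) absorbed by rescaling the kept columns;
            # a zero initial coefficient means infinite weight, i.e. the covariate drops
            Xw = Xs[:, keep] * np.abs(init[keep])
            coef_w, alpha = _lasso_fit(Xw, y, self.cv_folds, seed)
            beta[keep] = coef_w * np.abs(init[keep])
            return beta / sd, alpha
        raise AssertionError(f"unreachable engine {self.name!r}")
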