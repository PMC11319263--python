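"""L1-penalized whole-genome regression.

The engine minimizes (1/2n)||y - b0 - X b||^2 + lambda ||b||_1 with an
unpenalized intercept and internally standardized markers; the penalty
strength is chosen by inner k-fold cross-validation (minimum-MSE rule)
over a log-spaced path from lambda_max down a fixed number of decades.
Coordinate descent is delegated to scikit-learn's Lasso/LassoCV, which
optimize exactly this objective; coefficients are reported on the original
marker scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold

from .base import GPModel

__all__ = ["LassoSettings", "LassoModel", "lasso_max_lambda"]


@dataclass(frozen=True)
class LassoSettings:
    lambda_: float | None = None   # fixed penalty; None = inner-CV selection
    n_lambdas: int = 100
    path_decades: float = 4.0
    inner_folds: int = 5
    standardize: bool = True
    seed: int = 0


def lasso_max_lambda(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty for which all coefficients are exactly zero:
    lambda_max = max_j |x_j' (y - ybar)| / n."""
    yc = y - y.mean()
    return float(np.max(np.abs(X.T @ yc)) / len(y))


class LassoModel(GPModel):
    """LASSO engine; multi-target fits are independent per-column fits."""

    def __init__(self, settings: LassoSettings | None = None):
        self.settings = settings or LassoSettings()
        self.intercepts_: np.ndarray | None = None
        self.coefs_: np.ndarray | None = None  # (p, m), original scale
        self.lambdas_: list[float] = []

    def _standardize(self, X: np.ndarray):
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0] = 1.0
        return (X - mean) / scale, mean, scale

    def _fit_column(self, Xs: np.ndarray, y: np.ndarray):
        s = self.settings
        n = len(y)
        if y.std() == 0:
            warnings.warn("constant target: fitting intercept-only model", stacklevel=2)
            return float(y.mean()), np.zeros(Xs.shape[1]), 0.0
        if s.lambda_ == 0.0:
            A = np.column_stack([np.ones(n), Xs])
            beta, *_ = np.linalg.lstsq(A, y, rcond=None)
            return float(beta[0]), beta[1:], 0.0
        if s.lambda_ is not None:
            model = Lasso(alpha=s.lambda_, fit_intercept=True, max_iter=100000, tol=1e-10)
            model.fit(Xs, y)
            return float(model.intercept_), model.coef_.copy(), float(s.lambda_)
        if n < 2 * s.inner_folds:
            raise ValueError(f"need n >= {2 * s.inner_folds} for {s.inner_folds}-fold inner CV")
        lam_max = lasso_max_lambda(Xs, y)
        path = np.geomspace(lam_max, lam_max * 10 ** (-s.path_decades), s.n_lambdas)
        cv = KFold(n_splits=s.inner_folds, shuffle=True, random_state=s.seed)
        model = LassoCV(alphas=path, cv=cv, fit_intercept=True, max_iter=5000, tol=1e-4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # convergence chatter on dense paths
            model.fit(Xs, y)
        return float(model.intercept_), model.coef_.copy(), float(model.alpha_)

    def _fit(self, X: np.ndarray, Y: np.ndarray) -> None:
        if self.settings.standardize:
            Xs, mean, scale = self._standardize(X)
        else:
            Xs, mean, scale = X, np.zeros(X.shape[1]), np.ones(X.shape[1])
        intercepts, coefs = [], []
        self.lambdas_ = []
        for k in range(Y.shape[1]):
            b0_s, beta_s, lam = self._fit_column(Xs, Y[:, k])
            beta = beta_s / scale
            intercepts.append(b0_s - mean @ beta)
            coefs.append(beta)
            self.lambdas_.append(lam)
        self.intercepts_ = np.array(intercepts)
        self.coefs_ = np.column_stack(coefs)

    def _predict(self, X: np.ndarray) -> np.ndarray:
        return X @ self.coefs_ + self.intercepts_

    def kkt_residual(self, X, y, target: int = 0) -> float:
        """Max KKT violation |x_j' r| / n - lambda over excluded markers
        (should be <= ~0 for a converged solution)."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if self.settings.standardize:
            Xs, _, scale = self._standardize(X)
            beta = self.coefs_[:, target] * scale  # back to standardized scale
        else:
            Xs, beta = X, self.coefs_[:, target]
        lam = self.lambdas_[target]
        r = y - y.mean() - (Xs - Xs.mean(axis=0)) @ beta
        grad = np.abs(Xs.T @ r) / len(y)
        excluded = beta == 0
        if not excluded.any():
            return 0.0
        return float(np.max(grad[excluded]) - lam)
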