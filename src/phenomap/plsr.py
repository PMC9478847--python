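"""Partial least squares regression via NIPALS, with chemometric metrics.

The latent-variable decomposition is kept in score/loading form,

    X = A B' + C        (predictor scores A, loadings B, residual C)
    Y = D E' + F        (response scores D, loadings E, residual F)
    D = A G + H         (inner least-squares relation)

from which the regression vector ``K`` (beta coefficients) and intercept
are assembled so that ``y_hat = (x - mean_x) @ K + intercept``. NIPALS
extracts one component at a time — weight vector from the X'y
covariance, score, loading, then rank-one deflation — so successive
scores are mutually orthogonal and models are nested in the number of
latent variables.

Metrics follow chemometric convention: R^2 = 1 - RSS/TSS; SEC (standard
error of calibration) uses ``n - n_lv - 1`` degrees of freedom; SEP
(standard error of prediction) is the bias-corrected residual SD on the
validation set; plain RMSE and bias are reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import KFold

from .errors import DegenerateTargetError, GridMismatchError, RankError

__all__ = [
    "PLSRegressionNIPALS",
    "FitMetrics",
    "fit_plsr",
    "select_n_components",
    "evaluate",
]


@dataclass
class FitMetrics:
    """Calibration/validation figures of merit, all in mg/g where dimensional."""

    r2_cal: float = float("nan")
    sec: float = float("nan")
    r2_val: float = float("nan")
    sep: float = float("nan")
    rmse: float = float("nan")
    bias: float = float("nan")

    def merge(self, other: "FitMetrics") -> "FitMetrics":
        """Combine a calibration-side and a validation-side evaluation."""
        out = FitMetrics(**vars(self))
        for name, val in vars(other).items():
            if np.isnan(getattr(out, name)) and not np.isnan(val):
                setattr(out, name, val)
            elif not np.isnan(val) and name in ("rmse", "bias"):
                setattr(out, name, val)  # prefer validation rmse/bias
        return out

    def to_dict(self) -> dict:
        return {k: float(v) for k, v in vars(self).items()}


class PLSRegressionNIPALS(RegressorMixin, BaseEstimator):
    """Univariate-response PLSR fitted by NIPALS.

    Parameters
    ----------
    n_components : int
        Number of latent variables to extract.

    Attributes
    ----------
    x_scores_, x_loadings_, x_weights_ : ndarray
        Score matrix A (n, a), loading matrix B (p, a), weights (p, a).
    y_scores_, y_loadings_ : ndarray
        Response scores D (n, a) and loadings E (a,).
    inner_coefs_ : ndarray
        Per-component inner regression of D on A.
    x_residual_, y_residual_ : ndarray
        Deflation residuals C and F.
    coef_ : ndarray, shape (p,)
        Regression vector K on centered predictors.
    intercept_ : float
    x_mean_, y_mean_ : centering means.
    """

    def __init__(self, n_components: int = 10):
        self.n_components = n_components

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n, p = X.shape
        if n < 2:
            raise ValueError("need at least two samples")
        if y.shape[0] != n:
            raise ValueError("X and y disagree on sample count")
        if np.std(y) < 1e-12:
            raise DegenerateTargetError("response has zero variance")
        a_max = min(n - 1, p)
        if not 1 <= self.n_components <= a_max:
            raise RankError(
                f"n_components={self.n_components} outside [1, {a_max}] "
                f"for n={n}, p={p}"
            )

        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = float(y.mean())
        Xc = X - self.x_mean_
        yc = y - self.y_mean_

        A = self.n_components
        W = np.zeros((p, A))
        P = np.zeros((p, A))
        T = np.zeros((n, A))
        U = np.zeros((n, A))
        q = np.zeros(A)
        inner = np.zeros(A)
        for a in range(A):
            w = Xc.T @ yc
            nw = np.linalg.norm(w)
            if nw < 1e-12:
                raise RankError(
                    f"X'y covariance vanished at component {a + 1}; "
                    "reduce n_components"
                )
            w /= nw
            t = Xc @ w
            tt = float(t @ t)
            if tt < 1e-12:
                raise RankError(f"zero-variance score at component {a + 1}")
            pvec = Xc.T @ t / tt
            qa = float(yc @ t) / tt
            W[:, a], P[:, a], T[:, a], q[a] = w, pvec, t, qa
            U[:, a] = yc  # response score before deflation (E normalized to 1)
            inner[a] = qa
            Xc = Xc - np.outer(t, pvec)
            yc = yc - qa * t

        self.x_weights_ = W
        self.x_loadings_ = P
        self.x_scores_ = T
        self.y_scores_ = U
        self.y_loadings_ = q
        self.inner_coefs_ = inner
        self.x_residual_ = Xc
        self.y_residual_ = yc
        self.coef_ = beta_from_decomposition(W, P, q, self.n_components)
        # predict() centers X by x_mean_, so the intercept is the response mean
        self.intercept_ = self.y_mean_
        self.n_features_in_ = p
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        one_d = X.ndim == 1
        if one_d:
            X = X[None, :]
        if X.shape[1] != self.coef_.shape[0]:
            raise GridMismatchError(
                f"model expects {self.coef_.shape[0]} bands, got {X.shape[1]}"
            )
        out = (X - self.x_mean_) @ self.coef_ + self.intercept_
        return float(out[0]) if one_d else out


def beta_from_decomposition(W: np.ndarray, P: np.ndarray, q: np.ndarray, a: int) -> np.ndarray:
    """Regression vector for the first *a* components: W_a (P_a' W_a)^-1 q_a."""
    Wa, Pa, qa = W[:, :a], P[:, :a], q[:a]
    return Wa @ np.linalg.solve(Pa.T @ Wa, qa)


def fit_plsr(X, y, n_lv: int) -> PLSRegressionNIPALS:
    """Functional wrapper: fit a NIPALS PLSR model with ``n_lv`` components."""
    return PLSRegressionNIPALS(n_components=n_lv).fit(X, y)


def select_n_components(
    X,
    y,
    k_folds: int = 5,
    max_lv: int = 15,
    seed: int = 0,
) -> int:
    """Latent-variable count by k-fold cross-validation and the one-SE rule.

    Returns the smallest component count whose mean CV RMSE lies within
    one standard error of the global minimum. Deterministic given seed.
    """
    if max_lv < 1:
        raise ValueError("max_lv must be >= 1")
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    a_cap = min(max_lv, p, n - n // k_folds - 1)
    if a_cap < 1:
        raise ValueError("not enough samples per fold for even one component")

    kf = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
    fold_rmse = np.full((k_folds, a_cap), np.nan)
    for fi, (tr, te) in enumerate(kf.split(X)):
        # a fold's training data may have lower rank than a_cap; back off
        a_fold = a_cap
        while True:
            try:
                model = PLSRegressionNIPALS(n_components=a_fold).fit(X[tr], y[tr])
                break
            except RankError:
                a_fold -= 1
                if a_fold < 1:
                    raise
        Xte_c = X[te] - model.x_mean_
        for a in range(1, a_cap + 1):
            beta = beta_from_decomposition(
                model.x_weights_, model.x_loadings_, model.y_loadings_, min(a, a_fold)
            )
            pred = Xte_c @ beta + model.y_mean_
            fold_rmse[fi, a - 1] = float(np.sqrt(np.mean((y[te] - pred) ** 2)))
    mean_rmse = fold_rmse.mean(axis=0)
    best = int(np.argmin(mean_rmse))
    se = float(fold_rmse[:, best].std(ddof=1) / np.sqrt(k_folds))
    within = np.flatnonzero(mean_rmse <= mean_rmse[best] + se)
    return int(within[0]) + 1


def evaluate(y, y_hat, n_lv: int, partition: str = "val") -> FitMetrics:
    """Figures of merit for one partition.

    Calibration: fills ``r2_cal`` and SEC (``sqrt(RSS/(n - n_lv - 1))``).
    Validation: fills ``r2_val`` and the bias-corrected SEP
    (``sqrt(sum((e - e_bar)^2)/(n - 1))``). RMSE and bias always.
    """
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.shape != y_hat.shape or y.size < 2:
        raise ValueError("y and y_hat must share a length >= 2")
    e = y_hat - y
    rss = float(e @ e)
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss < 1e-15:
        raise DegenerateTargetError("zero total sum of squares")
    r2 = 1.0 - rss / tss
    n = y.size
    rmse = float(np.sqrt(rss / n))
    bias = float(e.mean())
    m = FitMetrics(rmse=rmse, bias=bias)
    if partition == "cal":
        dof = n - n_lv - 1
        if dof < 1:
            raise ValueError("too few calibration samples for the SEC dof")
        m.r2_cal = r2
        m.sec = float(np.sqrt(rss / dof))
    elif partition == "val":
        m.r2_val = r2
        m.sep = float(np.sqrt(np.sum((e - e.mean()) ** 2) / (n - 1)))
    else:
        raise ValueError("partition must be 'cal' or 'val'")
    return m
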