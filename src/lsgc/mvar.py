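"""Least-squares fitting of multivariate autoregressive (MVAR) models.

A K-variate order-p MVAR model writes each observation as a linear
combination of the p previous state vectors plus innovation noise,

    y(n) = sum_{r=1..p} A_r y(n-r) + e(n),    n = p+1, ..., N.

Rows are mean-centered before fitting (no intercept term), the coefficient
matrices are the exact multivariate least-squares solution obtained through
an SVD-based orthogonal decomposition, and the residual covariance uses the
maximum-likelihood 1/(N-p) normalization.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import TimeSeriesMatrix, _as_values

__all__ = [
    "MVARModel",
    "InfeasibleOrderError",
    "feasible_order",
    "fit_mvar",
    "residual_covariance",
    "select_order_aic",
]


class InfeasibleOrderError(ValueError):
    """The estimation equation would be singular: N - p < K * p."""


@dataclass
class MVARModel:
    """Fitted MVAR model: ``y(n) = yhat(n) + e(n)`` for n > p.

    A         : list of p (K, K) coefficient matrices A_1 ... A_p
    fitted    : (K, N-p) one-step predictions for n = p+1 ... N
    residuals : (K, N-p) prediction errors e
    sigma     : (K, K) residual covariance, normalized by N - p
    cond      : condition number of the lag-stacked regressor matrix
    mean      : (K,) row means removed before fitting
    """

    p: int
    A: list[np.ndarray]
    fitted: np.ndarray
    residuals: np.ndarray
    sigma: np.ndarray
    cond: float
    mean: np.ndarray

    @property
    def K(self) -> int:
        return self.A[0].shape[0]


def feasible_order(K: int, N: int, p: int) -> bool:
    """True iff a K-variate order-p fit on N samples is non-singular,
    i.e. ``N - p >= K * p``."""
    if K <= 0 or N <= 0 or p <= 0:
        raise ValueError("K, N, p must be positive integers")
    return N - p >= K * p


def _lag_stack(y: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Return targets Y = y[:, p:] and regressors X (K*p, N-p) with the
    lag-r block of X holding y(n-r)."""
    K, N = y.shape
    X = np.vstack([y[:, p - r : N - r] for r in range(1, p + 1)])
    return y[:, p:], X

def fit_mvar(y, p: int, *, allow_singular: bool = False) -> MVARModel:
    """Multivariate least-squares fit of an order-p MVAR model.

    Parameters
    ----------
    y : (K, N) array or TimeSeriesMatrix
        Observed series, one row per variable.  Rows are mean-centered
        internally.
    p : int
        Model order.
    allow_singular : bool
        Permit a rank-deficient regressor matrix and return the minimum-
        norm least-squares solution (needed when the series matrix itself
        is rank-deficient, e.g. a full-dimensional orthogonal rotation of
        a reduced data set).  The fitted values are unique regardless.

    Raises
    ------
    InfeasibleOrderError
        If ``N - p < K * p`` (singular estimation equation).
    np.linalg.LinAlgError
        If the regressors are rank-deficient and ``allow_singular`` is
        False; the message reports the condition number.
    """
    vals = _as_values(y)
    K, N = vals.shape
    if not feasible_order(K, N, p):
        raise InfeasibleOrderError(
            f"order {p} infeasible for K={K}, N={N}: requires N - p >= K * p"
        )
    mean = vals.mean(axis=1)
    yc = vals - mean[:, None]
    Y, X = _lag_stack(yc, p)
    # least squares on the (N-p, K*p) design; SVD route, rank-revealing
    coef, _, rank, sv = np.linalg.lstsq(X.T, Y.T, rcond=None)
    cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else np.inf
    if rank < X.shape[0] and not allow_singular:
        raise np.linalg.LinAlgError(
            f"rank-deficient regressor matrix (rank {rank} < {X.shape[0]}, "
            f"condition number {cond:.3e}); pass allow_singular=True to use "
            f"the minimum-norm solution"
        )
    coef = coef.T  # (K, K*p)
    fitted = coef @ X
    resid = Y - fitted
    A = [coef[:, (r - 1) * K : r * K] for r in range(1, p + 1)]
    sigma = residual_covariance(resid)
    return MVARModel(
        p=p, A=A, fitted=fitted, residuals=resid, sigma=sigma, cond=cond, mean=mean
    )


def residual_covariance(e: np.ndarray) -> np.ndarray:
    """Residual covariance ``e @ e.T / n_cols`` (ML normalization by N-p).

    The residuals are treated as zero-mean; the result is symmetric PSD
    by construction.
    """
    e = np.asarray(e, dtype=float)
    if e.ndim != 2 or e.shape[1] < 2:
        raise ValueError("residual matrix needs at least 2 columns")
    return e @ e.T / e.shape[1]


def select_order_aic(y, p_max: int) -> int:
    """Order selection by Akaike's information criterion.

    AIC(p) = (N - p) ln det Sigma(p) + 2 K^2 p, minimized over the feasible
    candidates p = 1 ... p_max.  Ties go to the smaller order.
    """
    vals = _as_values(y)
    K, N = vals.shape
    candidates = [p for p in range(1, p_max + 1) if feasible_order(K, N, p)]
    if not candidates:
        raise InfeasibleOrderError(
            f"no feasible order in 1..{p_max} for K={K}, N={N}"
        )
    best_p, best_aic = None, np.inf
    for p in candidates:
        model = fit_mvar(vals, p)
        sign, logdet = np.linalg.slogdet(model.sigma)
        aic = (N - p) * logdet + 2.0 * K * K * p if sign > 0 else np.inf
        if aic < best_aic:
            best_p, best_aic = p, aic
    return best_p
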