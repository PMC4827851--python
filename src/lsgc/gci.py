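"""Classical multivariate Granger causality index (GCI).

The GCI from series i to series j is the log ratio of the residual
variance of j in the reduced MVAR model (series i removed) to its residual
variance in the full model:

    gamma_{i->j} = ln( Sigma^{i-}_j / Sigma_j ).

One full D-variate fit plus one (D-1)-variate refit per removed series
(D + 1 least-squares fits in total).  This is the 100%-variance-explanation
reference that the PCA-embedded estimator reduces to at C = D.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mvar import InfeasibleOrderError, feasible_order, fit_mvar
from .simulate import _as_values

__all__ = ["ConnectivityMatrix", "classical_gci"]


@dataclass
class ConnectivityMatrix:
    """Directed (ls)GCI connectivity values.

    gamma : (D, D) matrix, ``gamma[j, i]`` holds gamma_{i->j}; same
        row = target / column = source orientation as the simulator's
        adjacency matrices.  The diagonal is undefined and set to NaN.
    estimator : "gci" for the classical index, "lsgc" otherwise
    n_components : C used by the low-dimensional fit (D for classical)
    """

    gamma: np.ndarray
    p: int
    n_components: int
    estimator: str
    var_explained: float = 1.0

    @property
    def D(self) -> int:
        return self.gamma.shape[0]

    def offdiag(self) -> np.ndarray:
        """Off-diagonal weights as a flat array (row-major)."""
        mask = ~np.eye(self.D, dtype=bool)
        return self.gamma[mask]


def classical_gci(y, p: int) -> ConnectivityMatrix:
    """Classical GCI matrix via full and row-deleted MVAR refits.

    In sample, every value is nonnegative: the reduced model's predictors
    are a subset of the full model's for each target equation.
    """
    vals = _as_values(y)
    D, N = vals.shape
    if not feasible_order(D, N, p):
        raise InfeasibleOrderError(
            f"classical GCI infeasible for D={D}, N={N}, p={p}: "
            f"requires N - p >= D * p"
        )
    full = fit_mvar(vals, p)
    sig_full = np.diag(full.sigma)
    gamma = np.full((D, D), np.nan)
    for i in range(D):
        keep = np.delete(np.arange(D), i)
        reduced = fit_mvar(vals[keep], p)
        sig_red = np.diag(reduced.sigma)
        gamma[keep, i] = np.log(sig_red / sig_full[keep])
    return ConnectivityMatrix(
        gamma=gamma, p=p, n_components=D, estimator="gci", var_explained=1.0
    )
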