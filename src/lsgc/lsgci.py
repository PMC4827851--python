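"""Large-scale Granger causality index (lsGCI).

The estimator makes fully multivariate Granger analysis tractable when the
number of series D approaches or exceeds the number of samples N: the data
are reduced to C leading principal components, a C-variate MVAR model is
fitted in component space, and its predictions are back-projected into
observation space, where residual variances are read off vertex by vertex.
Removing the influence of source i means deleting row i of the data
together with column i of the truncated mixing matrix W (a single PCA is
computed; no per-source re-decomposition).

Pipeline for a (D, N) matrix y and variance target v:

1. W, C  <- leading principal components reaching variance fraction v
2. x = W y;  fit C-variate MVAR of order p  ->  xhat
3. HD residuals  ehat(n) = y(n) - W^+ xhat(n)
4. for each source i:  x^{i-} = W^{i-} y^{i-}  (column i of W and row i of
   y deleted), fit MVAR -> xhat^{i-},
   ehat^{i-}(n) = y^{i-}(n) - (W^{i-})^+ xhat^{i-}(n)
5. gamma~_{i->j} = ln( Sigma~^{i-}_j / Sigma~_j ) from the diagonals of
   the HD residual covariances (n = p+1 ... N only)

At C = D the mixing matrix is square orthogonal and the procedure is
algebraically identical to the classical GCI.  For C < D the back-projected
models are not nested least-squares problems, so finite-sample values may
be negative; they are reported as computed, never clipped.
"""
from __future__ import annotations

import numpy as np

from .gci import ConnectivityMatrix
from .mvar import InfeasibleOrderError, fit_mvar
from .pca import pca_reduce
from .simulate import _as_values

__all__ = ["lsgc_matrix"]


def lsgc_matrix(y, p: int, var_target: float) -> ConnectivityMatrix:
    """lsGCI connectivity matrix at the given variance-explanation target.

    Requires ``N - p >= C * p`` for the retained component count C (the
    low-dimensional analogue of the classical feasibility condition).
    D + 1 low-dimensional MVAR fits are performed in total.
    """
    vals = _as_values(y)
    D, N = vals.shape
    yc = vals - vals.mean(axis=1, keepdims=True)
    red = pca_reduce(yc, var_target)
    C, W = red.C, red.W
    if N - p < C * p:
        raise InfeasibleOrderError(
            f"lsGCI infeasible: C={C} retained components need N - p >= C * p "
            f"(N={N}, p={p})"
        )
    x = W @ yc
    # x can be rank-deficient when C = D (rotation of centered data);
    # fitted values are unique, so the minimum-norm solution is fine
    full = fit_mvar(x, p, allow_singular=True)
    ehat = yc[:, p:] - W.T @ full.fitted  # W^+ = W.T (orthonormal rows)
    n_eff = ehat.shape[1]
    sig_full = np.einsum("ij,ij->i", ehat, ehat) / n_eff

    gamma = np.full((D, D), np.nan)
    for i in range(D):
        keep = np.delete(np.arange(D), i)
        Wi = W[:, keep]
        yi = yc[keep]
        xi = Wi @ yi
        reduced = fit_mvar(xi, p, allow_singular=True)
        ei = yi[:, p:] - np.linalg.pinv(Wi) @ reduced.fitted
        sig_red = np.einsum("ij,ij->i", ei, ei) / n_eff
        gamma[keep, i] = np.log(sig_red / sig_full[keep])

    estimator = "gci" if C == D else "lsgc"
    return ConnectivityMatrix(
        gamma=gamma,
        p=p,
        n_components=C,
        estimator=estimator,
        var_explained=red.var_explained,
    )
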