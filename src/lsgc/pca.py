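"""Principal component reduction of a multichannel time-series matrix.

The reduction keeps the smallest number C of leading components whose
cumulative eigenvalue fraction reaches the requested variance-explanation
target.  The truncated mixing matrix W (C x D, orthonormal rows) maps
observations to component scores, x = W y; its Moore-Penrose pseudoinverse
maps low-dimensional predictions back to observation space.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import _as_values

__all__ = ["PCAReduction", "pca_reduce", "back_project"]

# slack for "cumulative ratio >= target" so that a target of exactly 1.0 is
# reached at the numerical rank despite floating-point rounding
_RATIO_TOL = 1e-12


@dataclass
class PCAReduction:
    """Truncated PCA basis of a (D, N) data matrix.

    W             : (C, D) leading eigenvectors as rows, W @ W.T = I_C
    eigenvalues   : all D covariance eigenvalues, descending (zero-padded
                    past the numerical rank)
    C             : number of retained components
    var_explained : cumulative eigenvalue fraction of the first C
    """

    W: np.ndarray
    eigenvalues: np.ndarray
    C: int
    var_explained: float

    def transform(self, y: np.ndarray) -> np.ndarray:
        return self.W @ y


def pca_reduce(y, var_target: float) -> PCAReduction:
    """PCA basis retaining the smallest C with variance ratio >= var_target.

    ``y`` must be row-mean-centered (plain PCA of the covariance; no
    variance standardization).  Components are ordered by descending
    eigenvalue; each eigenvector's sign is fixed by making its largest-
    magnitude loading positive, so runs are bit-reproducible.  The computed
    Granger indices are invariant to this sign choice.
    """
    if not 0.0 < var_target <= 1.0:
        raise ValueError(f"var_target must lie in (0, 1], got {var_target}")
    vals = _as_values(y)
    D, N = vals.shape
    # economy SVD: left singular vectors = covariance eigenvectors; LAPACK
    # works on the smaller Gram side internally, identical by duality
    U, s, _ = np.linalg.svd(vals, full_matrices=False)
    lam = np.zeros(D)
    lam[: s.size] = s**2 / N
    ratios = np.cumsum(lam) / lam.sum()
    C = int(np.argmax(ratios >= var_target - _RATIO_TOL)) + 1
    W = U[:, :C].T.copy()
    flip = W[np.arange(C), np.abs(W).argmax(axis=1)] < 0
    W[flip] *= -1.0
    return PCAReduction(W=W, eigenvalues=lam, C=C, var_explained=float(ratios[C - 1]))


def back_project(x_hat: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Least-squares back-projection ``pinv(W) @ x_hat`` into observation
    space (for orthonormal-row W the pseudoinverse is just W.T)."""
    return np.linalg.pinv(W) @ x_hat
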