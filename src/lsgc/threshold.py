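"""Dichotomization of weighted connectivity matrices and edge-recovery ROC.

A weighted, complete directed connectivity matrix is turned into a binary
network either by a fixed percentile of the off-diagonal edge-weight
distribution (the deterministic multiple-threshold strategy; operating
points 90/95/98%) or, when a ground-truth network is available, by the
cutoff maximizing Cohen's kappa between the binarized matrix and the truth
adjacency.  Edge-recovery quality over the full threshold sweep is
summarized by an ROC curve whose status variable is edge presence in the
ground truth.  Self-connections are never candidate edges: the diagonal is
excluded from percentiles, kappa counts, and the ROC status set.
"""
from __future__ import annotations

from dataclasses import dataclass

import igraph as ig
import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve

from .gci import ConnectivityMatrix
from .simulate import ModularNetwork

__all__ = [
    "ROCResult",
    "percentile_threshold",
    "binarize",
    "cohens_kappa",
    "kappa_optimal_threshold",
    "check_connectedness",
    "roc_curve",
]


def _weights_and_mask(gamma) -> tuple[np.ndarray, np.ndarray]:
    mat = gamma.gamma if isinstance(gamma, ConnectivityMatrix) else np.asarray(gamma, float)
    mask = ~np.eye(mat.shape[0], dtype=bool)
    return mat, mask


def _truth_matrix(truth) -> np.ndarray:
    return truth.adjacency if isinstance(truth, ModularNetwork) else np.asarray(truth)


@dataclass
class ROCResult:
    """ROC sweep over all off-diagonal weights.

    thresholds descend; tpr/fpr are the cumulative rates along the sweep
    and auc is the trapezoidal area (equivalently the Mann-Whitney U
    statistic of edge vs. non-edge weights, up to ties).
    """

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


def percentile_threshold(gamma, q: float) -> float:
    """q-th percentile (linear interpolation) of the off-diagonal weights."""
    if not 0.0 < q < 100.0:
        raise ValueError("percentile q must lie in (0, 100)")
    mat, mask = _weights_and_mask(gamma)
    return float(np.percentile(mat[mask], q))


def binarize(gamma, threshold: float) -> np.ndarray:
    """Keep edges with weight strictly greater than the threshold.

    Strict ">" means a q-percentile threshold removes about q% of the
    candidate edges; ties at the threshold are dropped.  The diagonal is
    always zero.  Orientation follows the connectivity matrix: entry
    (j, i) set means the directed edge i -> j survives.
    """
    mat, mask = _weights_and_mask(gamma)
    out = ((mat > threshold) & mask).astype(np.int8)
    return out


def cohens_kappa(pred: np.ndarray, truth: np.ndarray) -> float:
    """Cohen's kappa between two boolean arrays of equal shape."""
    pred = np.asarray(pred, bool).ravel()
    truth = np.asarray(truth, bool).ravel()
    n = pred.size
    tp = np.sum(pred & truth)
    fp = np.sum(pred & ~truth)
    fn = np.sum(~pred & truth)
    tn = n - tp - fp - fn
    po = (tp + tn) / n
    pe = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / (n * n)
    if pe == 1.0:
        return 1.0 if po == 1.0 else 0.0
    return float((po - pe) / (1.0 - pe))


def kappa_optimal_threshold(gamma, truth) -> float:
    """Cutoff maximizing Cohen's kappa against the ground-truth adjacency.

    Every unique off-diagonal weight is swept as a candidate cutoff (edges
    kept where weight > cutoff); ties in kappa resolve to the lowest such
    cutoff.  Refuses degenerate truths (all edges present or absent),
    where kappa is undefined.
    """
    mat, mask = _weights_and_mask(gamma)
    tmat = _truth_matrix(truth)
    if tmat.shape != mat.shape:
        raise ValueError("connectivity and truth matrices must have equal shape")
    w = mat[mask]
    status = tmat[mask].astype(bool)
    n_pos = int(status.sum())
    n = status.size
    if n_pos == 0 or n_pos == n:
        raise ValueError("degenerate ground truth: kappa is undefined")

    order = np.argsort(w, kind="stable")
    w_sorted = w[order]
    s_sorted = status[order]
    uniq, first_idx = np.unique(w_sorted, return_index=True)
    # predictions positive for weight > uniq[k]: everything past the last
    # occurrence of uniq[k] in the sorted order
    cum_pos = np.concatenate([[0], np.cumsum(s_sorted)])
    starts = np.concatenate([first_idx[1:], [n]])  # index where w > uniq[k] begins
    tp = n_pos - cum_pos[starts]
    npred = n - starts
    fp = npred - tp
    fn = n_pos - tp
    tn = n - tp - fp - fn
    po = (tp + tn) / n
    pe = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / (n * n)
    with np.errstate(invalid="ignore", divide="ignore"):
        kappa = np.where(pe < 1.0, (po - pe) / (1.0 - pe), 0.0)
    best = int(np.argmax(kappa))  # argmax returns the first (lowest) maximizer
    return float(uniq[best])


def check_connectedness(net: np.ndarray) -> bool:
    """True iff the directed network is weakly connected (which also rules
    out isolated vertices)."""
    adj = _truth_matrix(net)
    g = ig.Graph.Adjacency(adj.T.tolist(), mode="directed")
    return bool(g.is_connected(mode="weak"))


def roc_curve(gamma, truth) -> ROCResult:
    """ROC of off-diagonal weights against edge presence in the truth."""
    mat, mask = _weights_and_mask(gamma)
    tmat = _truth_matrix(truth)
    if tmat.shape != mat.shape:
        raise ValueError("connectivity and truth matrices must have equal shape")
    status = tmat[mask].astype(int)
    if status.min() == status.max():
        raise ValueError("degenerate status set: ROC undefined")
    fpr, tpr, thr = _sk_roc_curve(status, mat[mask], drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(thresholds=thr, tpr=tpr, fpr=fpr, auc=auc)
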