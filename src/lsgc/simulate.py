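"""Ground-truth modular networks and MVAR benchmark time series.

The generator produces directed networks with a planted, non-overlapping
module structure (modules of 10-15 vertices, dense inside, sparse between),
parameterizes a first-order vector-autoregressive process on the network
support, and simulates stationary multivariate time series driven by
standard-normal innovations.

Adjacency convention used throughout the package: ``adjacency[i, j] == 1``
means there is a directed edge j -> i (row = target, column = source).
Column sums of the adjacency therefore equal total in-degrees, the
quantity bounded by 15 in the generation constraints.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GenerationError",
    "ModularNetwork",
    "ARCoefficients",
    "TimeSeriesMatrix",
    "P_INTRA",
    "inter_edge_probability",
    "generate_ground_truth_network",
    "assign_ar_coefficients",
    "check_stationarity",
    "simulate_mvar",
    "benchmark_system",
]

#: probability of a directed edge between two vertices of the same module
P_INTRA = 0.5
#: module sizes are drawn uniformly from {10, ..., 15}
MODULE_SIZE_MIN = 10
MODULE_SIZE_MAX = 15
#: each vertex keeps at least this many intra-module in- and out-edges
MIN_INTRA_DEGREE = 4
#: and at most this many inter-module in- and out-edges
MAX_INTER_DEGREE = 4
#: total in-degree (adjacency column sum) never exceeds this
MAX_IN_DEGREE = 15
#: number of planted modules per 100 vertices
MODULES_PER_100 = 8


class GenerationError(RuntimeError):
    """Constraint satisfaction failed within the allowed attempts."""


def inter_edge_probability(D: int) -> float:
    """Directed inter-module edge probability, p_ext = 3 / (D - 15).

    Calibrated so each vertex has on average three edges to and three
    edges from vertices of other modules, regardless of network size.
    """
    return 3.0 / (D - 15)


@dataclass
class ModularNetwork:
    """Directed binary network with planted module labels.

    adjacency : (D, D) int8 array, ``adjacency[i, j] = 1`` iff edge j -> i
    labels    : (D,) int array, planted module id of each vertex
    module_sizes : module cardinalities, in label order
    off_benchmark : True when D is not a multiple of 100 (sizes outside
        the benchmark grid are allowed but flagged)
    """

    adjacency: np.ndarray
    labels: np.ndarray
    module_sizes: list[int]
    seed: int | None = None
    off_benchmark: bool = False

    @property
    def D(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)

    def in_degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    def validate(self) -> None:
        """Raise ``ValueError`` unless every structural invariant holds."""
        A = self.adjacency
        D = self.D
        if A.shape != (D, D):
            raise ValueError("adjacency must be square")
        if np.any(np.diag(A) != 0):
            raise ValueError("self-loops are not allowed")
        if not np.isin(A, (0, 1)).all():
            raise ValueError("adjacency must be binary")
        sizes = np.asarray(self.module_sizes)
        if sizes.sum() != D:
            raise ValueError("module sizes must sum to D")
        if sizes.min() < MODULE_SIZE_MIN or sizes.max() > MODULE_SIZE_MAX:
            raise ValueError(
                f"module sizes must lie in [{MODULE_SIZE_MIN}, {MODULE_SIZE_MAX}]"
            )
        same = self.labels[:, None] == self.labels[None, :]
        intra = A * same
        inter = A * ~same
        if A.sum(axis=1).max() > MAX_IN_DEGREE:
            raise ValueError(f"an in-degree exceeds {MAX_IN_DEGREE}")
        if intra.sum(axis=1).min() < MIN_INTRA_DEGREE:
            raise ValueError("a vertex has fewer than 4 intra-module in-edges")
        if intra.sum(axis=0).min() < MIN_INTRA_DEGREE:
            raise ValueError("a vertex has fewer than 4 intra-module out-edges")
        if inter.sum(axis=1).max() > MAX_INTER_DEGREE:
            raise ValueError("a vertex has more than 4 inter-module in-edges")
        if inter.sum(axis=0).max() > MAX_INTER_DEGREE:
            raise ValueError("a vertex has more than 4 inter-module out-edges")


@dataclass
class ARCoefficients:
    """First-order AR coupling matrices on a network support.

    A         : list of p coefficient matrices (benchmark uses p = 1)
    eta       : maximum in-degree over all vertices; the nonzero coupling
                magnitude is 0.99 / eta, which bounds every column sum of
                |A^1| by 0.99 and thereby guarantees a stationary process
    rho_signs : matrix of iid uniform signs in {-1, +1}
    """

    A: list[np.ndarray]
    eta: int
    rho_signs: np.ndarray

    @property
    def p(self) -> int:
        return len(self.A)

    @property
    def D(self) -> int:
        return self.A[0].shape[0]


@dataclass
class TimeSeriesMatrix:
    """D x N matrix of observed series; row = vertex/series."""

    values: np.ndarray

    @property
    def D(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


def _as_values(y) -> np.ndarray:
    vals = y.values if isinstance(y, TimeSeriesMatrix) else np.asarray(y, dtype=float)
    if vals.ndim != 2:
        raise ValueError("time series must be a 2-D (D x N) matrix")
    return vals


def _sample_module_sizes(D: int, rng: np.random.Generator, max_attempts: int):
    if D % 100 == 0:
        m = MODULES_PER_100 * D // 100
    else:
        # off-benchmark sizes: aim at the mean module size 12.5
        m = max(1, round(D / 12.5))
        m = max(m, math.ceil(D / MODULE_SIZE_MAX))
        m = min(m, D // MODULE_SIZE_MIN)
    if not (MODULE_SIZE_MIN * m <= D <= MODULE_SIZE_MAX * m):
        raise GenerationError(
            f"no partition of D={D} into {m} modules of size "
            f"{MODULE_SIZE_MIN}-{MODULE_SIZE_MAX} exists"
        )
    for _ in range(max_attempts):
        sizes = rng.integers(MODULE_SIZE_MIN, MODULE_SIZE_MAX + 1, size=m)
        if sizes.sum() == D:
            return [int(s) for s in sizes]
    raise GenerationError(f"module-size sampling failed after {max_attempts} attempts")


def _intra_block(s: int, rng: np.random.Generator) -> np.ndarray:
    """Bernoulli(p_int) block repaired to intra in/out degree >= 4."""
    B = (rng.random((s, s)) < P_INTRA).astype(np.int8)
    np.fill_diagonal(B, 0)
    while True:
        in_def = np.flatnonzero(B.sum(axis=1) < MIN_INTRA_DEGREE)
        out_def = np.flatnonzero(B.sum(axis=0) < MIN_INTRA_DEGREE)
        if in_def.size == 0 and out_def.size == 0:
            return B
        if in_def.size:
            i = int(rng.choice(in_def))
            cand = np.flatnonzero(B[i] == 0)
            cand = cand[cand != i]
            B[i, int(rng.choice(cand))] = 1
        if out_def.size:
            j = int(rng.choice(out_def))
            cand = np.flatnonzero(B[:, j] == 0)
            cand = cand[cand != j]
            B[int(rng.choice(cand)), j] = 1


def _cap_inter_degrees(inter: np.ndarray, rng: np.random.Generator) -> None:
    """Remove random excess inter-module edges so in/out degrees <= 4."""
    for axis in (1, 0):
        deg = inter.sum(axis=axis)
        for v in np.flatnonzero(deg > MAX_INTER_DEGREE):
            row = inter[v] if axis == 1 else inter[:, v]
            ones = np.flatnonzero(row)
            drop = rng.choice(ones, size=int(deg[v]) - MAX_INTER_DEGREE, replace=False)
            row[drop] = 0


def _repair_column_sums(
    intra: np.ndarray, inter: np.ndarray, rng: np.random.Generator
) -> bool:
    """Delete in-edges of overloaded vertices until all in-degrees <= 15.

    Intra-module edges are removed first, but only while both endpoints
    keep at least 4 intra edges in the affected direction; otherwise an
    inter-module in-edge is removed (inter edges have no lower bound).
    """
    for _ in range(10 * intra.shape[0] * MAX_IN_DEGREE):
        total_in = intra.sum(axis=1) + inter.sum(axis=1)
        over = np.flatnonzero(total_in > MAX_IN_DEGREE)
        if over.size == 0:
            return True
        i = int(rng.choice(over))
        intra_out = intra.sum(axis=0)
        removable = np.flatnonzero(intra[i])
        removable = removable[intra_out[removable] > MIN_INTRA_DEGREE]
        if intra[i].sum() > MIN_INTRA_DEGREE and removable.size:
            intra[i, int(rng.choice(removable))] = 0
        else:
            inter_sources = np.flatnonzero(inter[i])
            inter[i, int(rng.choice(inter_sources))] = 0
    return False


def generate_ground_truth_network(
    D: int, seed: int, max_attempts: int = 10_000
) -> ModularNetwork:
    """Generate one constraint-satisfying modular ground-truth network.

    Intra-module edges are drawn with probability 0.5, inter-module edges
    with 3 / (D - 15); the draw is then locally repaired until every vertex
    has >= 4 intra-module in- and out-edges, <= 4 inter-module in- and
    out-edges, and total in-degree <= 15.  Constraints are never silently
    relaxed: if repair fails, a fresh draw is made, and after
    ``max_attempts`` failed draws a :class:`GenerationError` is raised.
    """
    if D <= 15:
        raise GenerationError("D must exceed 15 for p_ext = 3/(D-15) to be valid")
    ss = np.random.SeedSequence(seed)
    p_ext = inter_edge_probability(D)
    for attempt in range(max_attempts):
        rng = np.random.default_rng(ss.spawn(1)[0]) if attempt else np.random.default_rng(ss)
        try:
            sizes = _sample_module_sizes(D, rng, max_attempts)
        except GenerationError:
            raise
        labels = np.repeat(np.arange(len(sizes)), sizes)
        same = labels[:, None] == labels[None, :]

        intra = np.zeros((D, D), dtype=np.int8)
        offset = 0
        for s in sizes:
            sl = slice(offset, offset + s)
            intra[sl, sl] = _intra_block(s, rng)
            offset += s

        inter = ((rng.random((D, D)) < p_ext) & ~same).astype(np.int8)
        _cap_inter_degrees(inter, rng)
        if not _repair_column_sums(intra, inter, rng):
            continue

        net = ModularNetwork(
            adjacency=(intra + inter).astype(np.int8),
            labels=labels,
            module_sizes=sizes,
            seed=seed,
            off_benchmark=(D % 100 != 0),
        )
        try:
            net.validate()
        except ValueError:
            continue
        return net
    raise GenerationError(
        f"network generation failed after {max_attempts} attempts (D={D})"
    )


def assign_ar_coefficients(net: ModularNetwork, seed: int) -> ARCoefficients:
    """Place AR(1) couplings rho * 0.99 / eta on the network support.

    ``eta`` is the maximum in-degree (maximum adjacency column sum, <= 15)
    and ``rho`` is an iid uniform sign.  Every column sum of |A^1| is then
    at most eta * 0.99 / eta = 0.99 < 1, so the induced 1-norm bound makes
    the AR(1) process provably stationary at every network size.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    A = net.adjacency.astype(float)
    eta = int(net.in_degrees().max())
    rho = rng.choice(np.array([-1.0, 1.0]), size=A.shape)
    A1 = rho * (0.99 / eta) * A if eta > 0 else np.zeros_like(A)
    return ARCoefficients(A=[A1], eta=eta, rho_signs=rho)


def check_stationarity(coeffs: ARCoefficients) -> float:
    """Spectral radius of the p*D companion matrix (< 1 means stationary)."""
    p, D = coeffs.p, coeffs.D
    if p == 1:
        comp = coeffs.A[0]
    else:
        comp = np.zeros((p * D, p * D))
        comp[:D] = np.hstack(coeffs.A)
        comp[D:, :-D] = np.eye((p - 1) * D)
    return float(np.abs(np.linalg.eigvals(comp)).max())


def simulate_mvar(
    coeffs: ARCoefficients, N: int, burn_in: int = 500, seed: int = 0
) -> TimeSeriesMatrix:
    """Simulate N samples of the AR process with standard-normal innovations.

    The state starts at zero and ``burn_in`` initial samples are discarded
    to remove the transient.  Non-stationary coefficient sets are refused.
    """
    radius = check_stationarity(coeffs)
    if radius >= 1.0:
        raise ValueError(
            f"refusing to simulate a non-stationary process (spectral radius "
            f"{radius:.4f} >= 1)"
        )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    D, p = coeffs.D, coeffs.p
    total = burn_in + N
    y = np.zeros((D, total + p))
    innov = rng.standard_normal((D, total))
    for n in range(p, total + p):
        acc = innov[:, n - p]
        for r, Ar in enumerate(coeffs.A, start=1):
            acc = acc + Ar @ y[:, n - r]
        y[:, n] = acc
    return TimeSeriesMatrix(values=y[:, p + burn_in :].copy())


def benchmark_system(
    D: int,
    N: int = 1000,
    seed: int = 0,
    burn_in: int = 500,
    max_regenerations: int = 100,
) -> tuple[ModularNetwork, ARCoefficients, TimeSeriesMatrix]:
    """Network + coefficients + series for one benchmark realization.

    A single seed drives three independent deterministic sub-streams
    (network topology, coupling signs, innovations).  In the unlikely event
    of a non-stationary coefficient draw, the signs are redrawn with an
    incremented sub-seed; the topology is kept.
    """
    ss = np.random.SeedSequence(seed)
    net_seed, sign_seed, innov_seed = [int(c.generate_state(1)[0] >> 1) for c in ss.spawn(3)]
    net = generate_ground_truth_network(D, seed=net_seed)
    for k in range(max_regenerations):
        coeffs = assign_ar_coefficients(net, seed=sign_seed + k)
        if check_stationarity(coeffs) < 1.0:
            break
    else:  # pragma: no cover - unreachable under the 0.99/eta scaling
        raise GenerationError("no stationary coefficient draw found")
    series = simulate_mvar(coeffs, N=N, burn_in=burn_in, seed=innov_seed)
    return net, coeffs, series
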