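# Methods

## The estimation problem

Classical multivariate Granger causality quantifies directed influence
between the components of a D-variate time series through vector
autoregressive (MVAR) modeling: a series Y_i Granger-causes Y_j if removing
Y_i's past from the model increases Y_j's one-step prediction error.  With

    Y(n) = Σ_{r=1..p} A_r Y(n−r) + E(n),    n = p+1 … N,

fitted by multivariate least squares, the Granger causality index (GCI) is

    γ_{i→j} = ln( Σ^{i−}_j / Σ_j ),

the log ratio of the residual variance of Y_j in the (D−1)-variate model
with row i deleted to its residual variance in the full model.  The least
squares problem is solvable only when N − p ≥ D·p; for spatially
high-resolution recordings (e.g. voxel-level fMRI, D in the thousands,
N a few hundred) this fails outright.

## Large-scale GCI (lsGCI)

The large-scale estimator embeds a PCA dimension reduction inside the MVAR
step while keeping the connectivity readout in the original space:

1. Reduce: x = W·y, with W the C×D matrix of leading principal-component
   loadings (orthonormal rows), C chosen as the smallest count whose
   cumulative eigenvalue fraction reaches the variance-explanation target.
2. Model: fit a C-variate MVAR of order p to x (feasible when
   N − p ≥ C·p), giving predictions x̂.
3. Back-project: ê(n) = y(n) − W⁺·x̂(n), with W⁺ the Moore–Penrose
   pseudoinverse; residual variances are now per-vertex.
4. Remove a source: delete row i of y together with column i of W,
   x^{i−} = W^{i−}·y^{i−}, refit, and back-project with (W^{i−})⁺.
5. Read off γ̃_{i→j} = ln(Σ̃^{i−}_j / Σ̃_j) from the diagonals of the
   high-dimensional residual covariances.

One PCA is computed per data set; source removal reuses it by column
deletion (the variant with a separate PCA per deletion is intentionally
not implemented).  D+1 low-dimensional fits are performed in total.  At
C = D the mixing matrix is square orthogonal and the procedure is
algebraically identical to the classical GCI — the package's primary
correctness gate asserts elementwise agreement to 1e−6 on benchmark draws
and to 1e−8 against an independent straight-line re-implementation.

Because the back-projected reduced models are not nested least-squares
problems, finite-sample γ̃ values can be negative; they are reported as
computed, never clipped.  Residual covariances are taken over n = p+1 … N
only, where residuals are defined.

### Numerical choices

- Rows are mean-centered before PCA and before every MVAR fit; no
  intercept is estimated.  PCA is computed on centered but
  *unstandardized* data (plain covariance PCA); per-row variance
  standardization is deliberately not applied to simulated benchmarks.
- The PCA basis comes from an economy SVD (LAPACK works on the smaller
  Gram side internally).  Eigenvector sign ambiguity is fixed by making
  each row's largest-magnitude loading positive; the Granger indices are
  invariant to this choice (asserted against an eigendecomposition-based
  reference with different sign conventions).
- MVAR least squares is solved by SVD (`lstsq`), rank-revealing, with a
  condition-number diagnostic.  A rank-deficient regressor matrix is
  refused unless the caller opts into the minimum-norm solution — needed
  at C = D, where the rotated data are exactly rank-deficient after
  centering; the fitted values (projections) are unique regardless.
- Residual covariance uses the maximum-likelihood 1/(N−p) normalization.
  The GCI is a ratio of diagonals, so the convention cancels there.
- AIC order selection minimizes (N−p)·ln det Σ(p) + 2·K²·p over feasible
  orders; ties go to the smaller order.

## The synthetic benchmark

### Ground-truth networks

Directed networks of D ∈ {100, 200, …, 800} vertices with 8 planted
modules per 100 vertices, module sizes uniform on {10, …, 15} (resampled
until they sum to D).  Edges are drawn independently: intra-module with
p_int = 0.5, inter-module with p_ext = 3/(D−15) (calibrated so each vertex
sends and receives on average three inter-module edges).  Constraints:
every vertex keeps ≥ 4 intra-module in- and out-edges, ≤ 4 inter-module
in- and out-edges, and total in-degree (adjacency column sum) ≤ 15.
Constraint satisfaction is by local repair — adding missing intra edges to
deficient vertices, deleting random excess inter edges, then trimming
overloaded columns (intra edges only while both endpoints stay above the
minimum, otherwise inter edges) — with a bounded number of whole-network
retries; failure raises an explicit error rather than relaxing anything.

Adjacency orientation: entry (i, j) = 1 means edge j → i, so column sums
are in-degrees — the axis all the degree bounds refer to.  One convention
is used for coefficients, connectivity matrices, and file output.

The conditional nature of constrained sampling means realized densities
deviate from the proposal probabilities (intra ≈ 0.525 rather than 0.5;
inter ≈ 0.029 rather than 0.035 at D = 100): a ≤ 4 cap on a mean-3 count
necessarily lowers its mean, and the intra minimum raises it.  This holds
for *any* generator honoring the constraints and is a property of the
benchmark design itself; the test suite documents it by asserting the
literal proposal probabilities, an assertion that the constrained ensemble
cannot meet.

### AR parameterization and simulation

On the network support, A¹_ij = ρ·0.99/η with ρ a uniform random sign and
η the maximum in-degree (≤ 15).  Every column sum of |A¹| is then at most
0.99, so the induced 1-norm — and hence the companion spectral radius — is
below 1 and the AR(1) process is provably stationary at every network
size, with comparable coupling strength across sizes.  (The superficially
similar scaling 0.99^η fails this: at D = 100 it yields spectral radii
near 3 on every draw, a divergent process.)  Stationarity is still
verified, not assumed: the companion spectral radius is computed for every
draw and non-stationary coefficient sets would be redrawn with an
incremented sub-seed (unreachable under this scaling, kept as a
safeguard).

Innovations are i.i.d. standard normal.  Simulation starts from a zero
state and discards a 500-sample burn-in (the slowest mode decays with
radius ≈ 0.25, so the transient is far below machine noise at that depth);
N = 1000 samples are retained.  One master seed drives three independent
sub-streams (topology, coupling signs, innovations) via seed-sequence
spawning, so each component is reproducible in isolation.

### What the generator does and does not emulate

The benchmark has linear dynamics, Gaussian innovations, binary coupling
of uniform magnitude, known model order p = 1, and clear-cut planted
modules.  Real recordings (the motivating application is resting-state
fMRI) add hemodynamic smoothing, measurement noise, non-stationarity,
unknown order, and modules of uncertain sharpness.  Passing benchmarks
therefore certifies the estimator's algebra, its feasibility behavior,
and module recoverability under the stated generative model — not
performance on any particular empirical modality.

## Dichotomization and evaluation

- Percentile thresholds (operating points 90/95/98%) are computed over
  off-diagonal weights with linear interpolation; edges are kept on
  strict ">" so the q-percentile removes ≈ q% of candidate edges (ties at
  the threshold drop).  Self-connections are never candidates.
- When ground truth is available, the cutoff maximizing Cohen's κ between
  the binarized matrix and the truth adjacency is found by sweeping every
  unique off-diagonal weight; κ ties resolve to the lowest cutoff.
  Degenerate truths (no edges, or all edges) are refused.
- ROC curves use edge presence as the status variable, excluding the
  diagonal; AUC is the trapezoidal area (equal to the Mann–Whitney
  U-statistic up to ties).
- Connectedness (weak connectivity of the directed network) is reported
  as a filter, never used to adjust a threshold automatically.

## Module detection

Seven detectors behind one interface; undirected algorithms receive the
symmetrized network (an arc in either direction becomes an edge).
Hierarchies and multi-level results are cut at maximal modularity;
stochastic detectors take explicit seeds.

- Leading eigenvector, directed and undirected: in-package recursive
  spectral bisection of the (symmetrized) Leicht–Newman directed
  modularity matrix, with greedy single-vertex fine-tuning of each split.
  On a symmetric input the directed modularity reduces exactly to the
  Newman–Girvan form, so one code path serves both variants.  igraph's
  undirected implementation omits the fine-tuning stage and measurably
  splits planted benchmark modules more often, which is why it is not
  used here.
- Louvain directed: leidenalg's directed-modularity optimizer (the
  canonical Louvain method is undirected; this is the documented
  interpretation of a "directed Louvain").
- Walktrap, fast greedy, undirected Louvain, Potts spin glass: igraph
  adapters.  Spin glass requires a connected input and refuses otherwise.
- Infomap is wired in behind a flag but excluded from default benchmark
  reports.

## Partition measures

Pair-count-based: Rand index, Hubert–Arabie adjusted Rand, mutual
information and variation of information (natural log), van Dongen
split-join distance.  Matching-based: modules of two partitions are paired
by minimizing total Jaccard distance (exact rectangular assignment);
the correctly-classified ratio counts vertices whose two module labels
are matched, with vertices of unmatched surplus modules counted as
misclassified — the convention that makes the measure well defined when
module counts differ.  Topology-aware: coverage (intra-module fraction of
directed edges), performance (correctly interpreted unordered vertex
pairs, with "linked" meaning an arc in either direction), Newman–Girvan /
Leicht–Newman modularity, and the partition edit distance (per matched
module pair, internal adjacency submatrices aligned on the union of the
two vertex sets with absent vertices as zero rows/columns, vectorized
row-major, Levenshtein-compared, summed).

For the correctly-classified ratio on lsGCI networks the reference
partition is the one the same algorithm detects on the ground-truth
network (the planted labels are the reference only for the ground-truth
networks themselves); the pipeline tabulates both variants.

## Study orchestration and problem sizes

`run_benchmark` derives per-realization seeds from the master seed by
seed-sequence spawning, tolerates and logs partial failures, and emits
tidy tables.  The default configuration matches the benchmark ensemble
(D = 100, N = 1000, p = 1, 100 realizations); the package's own acceptance
runs use 20 realizations — enough for stable medians of the per-algorithm
distributions (the AUC standard error at this size is ≈ 0.003) while
keeping a full desk run in minutes — via the same `--scale`/realization
controls available to any user.

## Known limitations

- Model order p = 1 for the generator; higher orders are supported by the
  fitting and selection code but not by the benchmark generator.
- No statistical significance testing of individual edges; thresholds are
  deterministic (percentile) or truth-referenced (κ-optimal).
- Classical GCI at large D (≥ 400 at N = 1000) is close to the
  feasibility boundary and increasingly ill-conditioned; the benchmark
  defaults stay at D = 100.
- The per-deletion-PCA lsGC variant is not implemented.
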