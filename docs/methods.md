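# Methods

## Model

A chromosome segment is represented as an ordered curve
X = (x_1, …, x_n), x_i ∈ ℝ³, where x_i is the spatial center of the i-th
genomic bin.  The observed single-cell Hi-C contact count between bins i
and j is modelled as an independent Poisson draw whose mean follows a
power law in the pairwise distance d_ij = ‖x_i − x_j‖:

    C_ij ~ Poisson(b · d_ij^a),   a < 0, b > 0.

The default exponent a = −3 comes from polymer physics; b only sets the
overall scale of the curve (rescaling X by γ is equivalent to replacing b
by γ^a b), so b = 1 is used for estimation and curves are reported up to
scale.  Dropping terms constant in X, the negative log-likelihood is

    g(X | C, a, b) = − Σ_{i<j} ( a c_ij log d_ij − b d_ij^a ).

Pairs with c_ij = 0 still contribute the repulsive term b d_ij^a;
diagonal entries are ignored everywhere.

Single-cell matrices are extremely sparse, so the maximum-likelihood
embedding is regularized by three priors:

* **Uniform spacing (h1).**  With L(X) the total polyline length and
  u_i = (n−1)‖x_{i+1} − x_i‖ / L(X) the gap lengths after rescaling the
  curve to length n−1, the u_i average exactly 1 and
  h1(X) = (1/(n−1)) Σ (u_i − 1)² is their variance.  It is zero iff all
  gaps are equal and is invariant to similarity transforms.  The divisor
  is the number of gaps, n−1; since mean(u) = 1 by construction this is a
  plain per-gap average, and the minimum is 0 for every n.
* **Smoothness (h2).**  The mean cosine of the interior bend angles,
  h2(X) = (1/(n−2)) Σ_{i=2}^{n−1} cos θ_i ∈ [−1, 1], equal to −1 exactly
  on straight monotone chains.
* **Bulk prior (h3).**  A population (bulk) Hi-C matrix C′ enters through
  its own normalized likelihood, (λ3 / M′) g(X | C′, a, b), with
  M = Σ_{i<j} c_ij and M′ its bulk analogue.  Algebraically this is
  absorbed into the data: with k = λ3 M / M′, the pair
  (C̃, b̃) = (C + k C′, (1+k) b) satisfies
  g(X|C,a,b)/M + (λ3/M′) g(X|C′,a,b) = g(X|C̃,a,b̃)/M, so the prior costs
  nothing extra at optimization time and fills zero entries of a sparse C
  with small population-informed values.

The working objective minimized over X is

    E(X) = g(X | C̃, a, b̃) / M + λ1 h1(X) + λ2 h2(X),

with documented default weights λ = (0.5, 1.0, 0.1) for real single-cell
matrices.  Simulation studies use the weights stated per experiment.

## Gradients

All three terms have analytic gradients, derived here by direct
differentiation and verified against central finite differences (the test
suite requires max relative error < 1e−5 at n = 50):

* ∂g/∂x_i = −a Σ_{j≠i} (c_ij − b d_ij^a) (x_i − x_j) / d_ij².
* ∂h1/∂s_k = (2/L)(u_k − 1 − h1) for gap length s_k, distributed onto the
  gap's endpoints along the unit gap direction (uses Σ(u_i − 1) = 0).
* ∂h2: standard differentiation of the normalized dot product at each
  interior vertex, accumulated on the three participating nodes.

Distances below ε = 1e−10 are clamped inside logs, powers and
normalizations, with a warning; random initializations may otherwise
place points arbitrarily close where d^a and log d diverge.

## Optimization

E is non-convex with many local minima.  Estimation is coarse-to-fine:

1. Recursively merge adjacent bin pairs (coarse entry = sum of mapped
   fine entries, counts landing on the coarse diagonal dropped, odd sizes
   leave a singleton last bin) until n ≤ `min_n` (default 64; smaller
   coarsest scales preserve more solution diversity across seeds).
2. Initialize the smallest problem from a standard multivariate normal.
3. Minimize with L-BFGS (limited-memory quasi-Newton, the practical BFGS
   realization at n of several hundred) using the analytic gradient.
4. Upsample the solution to the next finer size by placing nodes at
   uniformly spaced arc-length positions along the piecewise-linear curve
   (endpoints preserved) and repeat until full resolution.

The same λ vector is applied at every scale: both penalties are already
n-normalized, and M is recomputed from each coarsened matrix so the
likelihood term stays a per-contact average.  Convergence uses a
projected-gradient infinity-norm tolerance of 1e−7 with an iteration cap
of 20 000 per scale and L-BFGS memory 25; dense n = 100 problems
typically need 8 000–15 000 iterations to reach stationarity, which is
why the cap is set well above it.  `ftol` is effectively disabled so the
stop is gradient-based.  Returned curves are centered at the origin;
scale is left as produced (b fixes it arbitrarily).  A line-search
failure that would end above the starting energy returns the starting
point instead, so the descent contract E(final) ≤ E(init) holds at every
scale.

## Synthetic data

The simulator emulates a population of cells sharing a mean conformation
with coherent cell-to-cell variability:

* **Mean curve.**  Sum of 3–6 random-phase sinusoids per coordinate with
  1/f amplitude decay along the bin index, plus a gentle monotone drift,
  rescaled to unit mean gap.  Candidates are rejection-sampled until the
  curve is *self-avoiding* (non-adjacent nodes ≥ 0.8 gap units apart —
  chromatin fiber has excluded volume) and *compact* (radius of gyration
  ≤ 12 gap units, a territory-like fold rather than an extended thread).
  Both thresholds were fixed once as the realistic regime; heavily
  self-intersecting curves are neither physical nor identifiable from
  contact data.
* **Per-cell curves.**  mean + variability · Rg(mean) · field, where the
  field is a smooth unit-normalized low-frequency sinusoid field —
  coherent shape change, not i.i.d. per-node jitter.  Fields are re-drawn
  from the cell's own substream until the perturbed curve keeps a
  self-distance ≥ 0.5 gap units.  Default variability 0.15: visible shape
  differences between cells while all cells remain recognizably the same
  fold.  One master seed spawns per-cell substreams, so cell k is
  unchanged when K grows.
* **Contacts.**  C_ij ~ Poisson(b d_ij^a) independently for j > i,
  mirrored, zero diagonal.  b = 1e6 gives dense matrices (recovery
  regime), b = 10 the sparsity typical of single cells.  Bulk matrices
  are elementwise sums over cells, optionally leave-one-out.

What the generator does **not** emulate: genomic-distance-dependent
coverage biases, unmappable bins, translocations/multi-chromosome
contacts, or restriction-site digestion noise.  Passing tests therefore
demonstrate correctness of the estimator under the model's own
assumptions, not robustness to every artifact of real Hi-C.

## Experiments (desk-scale defaults)

Replication counts are roughly one tenth of a full study so the complete
suite runs on a single CPU in tens of minutes; all counts are arguments.

* **Dense recovery** — n = 100, a = −3, b = 1e6, λ = (0.001, 0.001, 0),
  20 single-scale runs from independent normal inits.  Expected: the
  best-of-ensemble solution aligns to the truth within a few percent of
  its radius of gyration, while other near-equal-energy minima show
  locally reflected substructures with much larger RMSD (energy and RMSD
  are only loosely correlated).
* **Prior sweep** — K = 100 simulated cells at b = 10, leave-one-out bulk,
  λ1 = λ2 = 0.1, λ3 ∈ grid including 0, 8 cells × 5 inits per value.
  Expected: mean RMSD drops as λ3 leaves 0; at very large λ3 the solution
  approaches the bulk-only structure, whose distance to an individual
  cell's truth is bounded below by the cell-to-cell variability.
* **Multiscale comparison** — n = 128, b = 10, λ1 = λ2 = 0.1, ten paired
  seeds; the same init seed drives a flat full-resolution run and the
  coarse-to-fine pipeline (coarsest scale 32).  Reported: per-seed final
  energy difference (flat − multiscale); positive mean means multiscale
  found lower energies.
* **Ensemble clustering** — 3 cells × 10 multiscale solutions at n = 64,
  b = 1000; pooled solutions clustered (average linkage) on the symmetric
  pairwise RMSD matrix.  Expected: cutting at k = 3 groups solutions by
  cell of origin; within-cell mean RMSD < between-cell mean RMSD.

## Shape space

Curves are compared after full similarity alignment: centering, optimal
scaling, and rotation over the full orthogonal group (reflections
allowed, since the likelihood cannot distinguish mirror images), i.e.
orthogonal Procrustes with no determinant correction.  RMSD divides by n
(root of the mean, not the sum).  Ground-truth comparisons scale the
solution onto the truth; pairwise ensemble comparisons first rescale both
curves to unit centered Frobenius norm, which makes the optimally scaled
distance exactly symmetric (one-sided scaling is not).  The pairwise
matrix is a symmetric premetric; the triangle inequality is not asserted.
Hierarchical clustering uses average linkage by default (configurable).

## Numerical and degenerate-input choices

* Symmetry of input matrices is required (tolerance 1e−9); diagonals are
  zeroed on load with a warning.
* M = 0 (no contacts) is a hard error at full resolution; coarse-scale M
  is recomputed from the coarsened matrix.
* Upsampling guarantees equal *arc-length* spacing; the Euclidean gap
  variance h1 of an upsampled curve is exactly 0 only for collinear
  curves and small (≪ 1) for smooth ones, because chords cut corners.
* Non-finite energy at an initialization triggers one perturbed retry,
  then an error.
* COO files are 0-based; upper-triangle entries suffice and are mirrored.

## Known limitations

* a and b are fixed inputs, never estimated from data.
* Curves with different bin counts cannot be compared (no resampling).
* Single-chromosome only; no inter-chromosomal contacts.
* The Poisson model ignores overdispersion; counts from merged bins are
  summed, which is exact for Poisson but would not be for a negative
  binomial extension.
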