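# Methods

## Model and procedure

The package treats chromosome structure inference as distance-geometry
optimization. A binned interaction matrix `F` (symmetric, non-negative;
diagonal ignored) is converted to target distances by the power law
`D_ij = F_ij^(-α)`, with `D_ij = ∞` wherever `F_ij = 0` — an absent contact
carries no distance constraint at all, it does not mean "far away". Each bin
is a point `P_j` in 3-space; the reconstruction moves points until pairwise
distances match the finite targets as well as possible.

The update is built from per-pair *error vectors*

    E_ij = unit(P_i − P_j) · (|P_i − P_j| − D_ij),

whose sign pulls a too-distant pair together and pushes a too-close pair
apart, aggregated per bin into a *resultant*

    E_j = Σ_{i : D_ij < ∞} w_ij E_ij,
    w_ij = coCC_ij / (S_j (N−1)^β),   S_j = Σ_{i : D_ij < ∞} coCC_ij,

where `coCC_ij` is the co-clustering coefficient of the pair in the contact
graph (see below) and `N` the number of bins. All bins are then moved
simultaneously, `P_j ← P_j + E_j`. The objective `F = Σ_j |E_j|` is recorded
every iteration; the run stops when `|F_t − F_{t−1}| < tol` or at `max_iter`.

**Normalization of the resultant.** The weights are normalized per bin by
`S_j`, making each step a damped convex combination of that bin's error
vectors. An unnormalized sum `Σ coCC_ij/(N−1)^β E_ij` scales like
`(N−1)^(1−β)` times the mean constraint violation for dense matrices and
diverges synchronously for any realistic `N` at small β (verified
numerically: overflow within ~90 iterations on a complete 100-bin contact
graph at β = 0.1). The normalized form keeps the documented semantics of
every tunable — coCC weighting of informative pairs, β as a pure
convergence-speed factor (larger = slower), convergence to ΔF < 1e-6 with
the default β = 0.1 — and reproduces the published noise-robustness
behavior of the method. This is the package's own resolution of an
under-specified update rule and the central numerical design decision.

**Co-clustering coefficient.** The finite entries of `D` define an
undirected graph (edge ⇔ observed contact). For bins i, j the union of
their neighbor sets `U_ij = N_i ∪ N_j` contains `k_ij` nodes; `e_ij` counts
*every* graph edge with both endpoints in `U_ij` (when i and j are adjacent
they belong to each other's neighbor sets, so the (i,j) edge itself
counts). Then `coCC_ij = 2 e_ij / (k_ij (k_ij − 1))`, defined as 0 when
`k_ij ≤ 1` (no clustering evidence). The matrix is computed once from the
data and held fixed: the graph depends only on which contacts were
observed, not on coordinates. Pairs with `D_ij = ∞` still have a defined
coCC but contribute nothing to the optimization. The all-pairs computation
uses a complement identity (`e_ij = m − Σ_{a∈C} deg a + e(C,C)` with
`C = V∖U_ij`) plus packed-bitset popcounts on the smaller of union/
complement supports; it is validated against a literal O(n⁴) set-based
recount in the tests. Quadratic memory and roughly cubic time limit
practical inputs to a few thousand bins per run.

## Parameters

| name | default | meaning |
|------|---------|---------|
| `alpha` | 0.5 | distance power-law exponent; 0.5 for real Hi-C counts, 1 for the simulation bench where frequencies are exactly reciprocal distances |
| `beta` | 0.1 | convergence factor ≥ 0; damps steps by `(N−1)^β`, larger = slower |
| `tol` | 1e-6 | threshold on the objective change ΔF (same units as F, i.e. length) |
| `max_iter` | 20000 | iteration cap |
| `seed` | none | seeds initial coordinates and degenerate-pair jitter; fixes the whole run bit-for-bit |
| `init_scale` | 1.0 | initial coordinates are uniform in a cube of side `init_scale ×` mean finite target distance |
| `smooth sigma` | auto (off) | per-chain Gaussian filter along bin order, visualization only |

## Numerical choices and degenerate inputs

- **Update scheme** is synchronous: all resultants are computed from the
  pre-step coordinates, then all bins move. This is order-independent and
  reproducible. At very small N it overshoots (two bins with one mutual
  constraint swap through their midpoint — covered by a test); at realistic
  N the averaged step is stable.
- **Coincident points** (separation < 1e-12) have no defined unit vector;
  the error vector becomes a seeded-random direction of magnitude `D_ij`,
  antisymmetric within the pair, pushing the points apart.
- **Isolated bins** (entire row of `D` infinite) are removed before
  optimization and reported as NaN rows in output files, keeping original
  bin numbering; a matrix with *only* isolated bins is rejected.
- **Divergence detection**: 100 consecutive objective increases, or any
  non-finite coordinate, abort with an error naming the iteration and
  suggesting a larger β. The first iteration has no ΔF and never stops the
  run.
- **No re-centering** during iteration; translational drift is irrelevant
  to a distance objective and is removed by superposition at evaluation.
- **Superposition** is Kabsch via SVD. Reflection is allowed by default
  (distance data cannot determine chirality); proper-rotation-only and
  uniform-scale fitting are options. Scale fitting requires ≥ 3
  non-collinear points.
- **Recovered-frequency SCC** uses only pairs with positive input
  frequency (zero frequency has no recoverable rank) and average ranks for
  ties. Evaluation always uses unsmoothed coordinates.

## Simulation bench

Six deterministic curves emulate chromatin morphologies of increasing
complexity: circle, open spiral and closed circular (torus-wound) spiral as
single chromosomes; replication fork, double helix and double spherical
helix as two-chromosome systems with both intra- and inter-chain contacts.
Only the shapes' names are canonical; the parameterizations here (unit
radii, 4-turn helices, 16-winding torus spiral, 8-winding spherical
spirals) are this package's own and are overridable — the test logic is
shape-independent because contacts are derived from the generated geometry
itself. Each structure defaults to 500 points, split 250/250 for
double-chain models. Two constructions avoid exact point coincidence, which
would make `F = 1/D` singular: the replication fork's two strands run
parallel at a 0.02 gap before the fork, and the spherical spirals sample
latitude with a half-step inset from the poles.

Contacts are reciprocal distances (`F = 1/|P_i − P_j|`), so `alpha = 1`
makes the frequency→distance conversion the exact inverse and noiseless
reconstruction is solvable to machine-level shape agreement. Noise is
multiplicative on distances *before* conversion to frequencies: each
pairwise distance is scaled by `(1 + r·s)`, `r ~ U[−1, 1]` drawn once per
unordered pair (symmetry preserved), `s ∈ [0, 1]`, floored at 1e-9 of the
original value against the `s = 1, r = −1` corner.

What this bench does *not* emulate: genomic-distance-dependent coverage
decay, zero-inflation/sparsity of real Hi-C matrices, normalization
artifacts, or polymer physics. A green simulation test therefore
establishes that the optimizer inverts its own forward model under
controlled noise — fidelity on real data is assessed separately via the
recovered-frequency SCC, which needs no ground-truth structure.

## Known limitations

Two behaviors of the stopping rule are worth knowing when benchmarking:

- **Planar structures converge slowly in their soft direction.** Out-of-plane
  displacements of a flat structure (e.g. the circle benchmark) change
  pairwise distances only to second order, so the restoring force vanishes
  near the optimum and the ΔF criterion can stop with a residual
  out-of-plane ripple of around a percent of the diameter while the in-plane
  shape (and the distance-PCC) is already exact. Running more iterations
  keeps shrinking it; raise `max_iter` and lower `tol` if sub-percent RMSD
  on planar inputs matters.
- **Occasional local optima on complex closed curves.** With random
  initialization a topologically intricate target (e.g. the torus-wound
  closed spiral) can settle into a folded configuration with a clearly
  elevated terminal objective. Comparing the terminal `F` across a few seeds
  identifies such runs immediately; keep the best of several seeds.

Other limitations:

- Dense `O(N²)` memory and per-iteration cost; thousands of bins per run is
  the practical ceiling, well below kilobase-resolution whole genomes.
- The contact graph of very sparse matrices can leave bins with zero coCC
  to every partner; such bins receive no update and retain their (random)
  initial placement.
- Absolute scale of a reconstruction is meaningful only through the power
  law; comparisons across methods with arbitrary output scale should
  enable scale fitting in the superposition.
- Chirality is unidentifiable from contacts; reported structures are
  arbitrary up to mirror image.
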