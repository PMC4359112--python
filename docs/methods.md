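# Methods

## The decomposition models

### Common-vector model

Given a genes × samples matrix M (m×n, finite entries, any scale), the
common-vector program is

    minimize ‖Y‖₁   subject to   x·ι + Y + Z = M,   ‖Z‖_F ≤ δ,

over x ∈ ℝ^m, Y, Z ∈ ℝ^{m×n}; ι is the all-one row vector.  The background
x·ι assigns each gene one level shared by every sample; Y collects sparse
sample-specific deviations; Z absorbs noise up to the Frobenius budget δ.
The L1 objective is the convex surrogate for foreground sparsity.  The
model differs from robust PCA in that the background is not merely
low-rank but constrained to this specific rank-one, column-constant form —
the right structure when one biological baseline underlies all samples of
a cohort.

A useful consequence at δ = 0: eliminating Y gives
min_x ‖M − x·ι‖₁, which decouples per gene into scalar L1 location
problems, so the optimal background level of each gene is the **median of
its row**.  The test suite uses this closed form as an independent check
on the iterative solver.

### Multi-condition low-rank model

For K condition matrices M₁..M_K of equal shape sharing one background,

    minimize ‖X‖* + Σᵢ ρᵢ‖Yᵢ‖₁   s.t.   X + Yᵢ + Zᵢ = Mᵢ,  ‖Zᵢ‖_F ≤ δ,

the nuclear norm ‖X‖* being the convex surrogate for background rank.
`common_vector=True` restricts X to x·ι; the nuclear term then plays no
role and is dropped, and at K = 1 the solver reproduces
`decompose_common_vector` exactly.  The non-convex rank/L0 analogue of
this program is documented for orientation but deliberately not solved;
only the convex relaxation is implemented.

### ADMM solver

Both programs are solved by the alternating direction method of
multipliers on the augmented Lagrangian

    ‖Y‖₁ − ⟨D, x·ι + Y + Z − M⟩ + (γ/2)‖x·ι + Y + Z − M‖_F²,

minimizing blocks in the fixed order x → Y → Z, then taking the dual step
D ← D − γ(x·ι + Y + Z − M).  Every block update is closed-form:

* x: row means of M − Y − Z + D/γ;
* Y: entrywise soft-thresholding at 1/γ (ρᵢ/γ in the multi-condition
  model) — the proximal operator of the L1 term;
* X (multi-condition): singular-value thresholding at 1/(Kγ) of the mean
  of the K per-condition targets — the proximal operator of the nuclear
  norm;
* Z: Euclidean projection onto the Frobenius ball of radius δ.

Reordering the blocks changes the iterates but not the convex optimum.

**Parameters.**

| parameter | default | meaning / rationale |
|---|---|---|
| δ | required | noise budget, in Frobenius-norm units of M; scale-dependent, so no universal default is meaningful.  δ=0 gives an exact split M = x·ι + Y.  δ at or above ‖M − row-mean background‖_F makes Y = 0 feasible — a valid, documented degenerate regime.  (On raw microarray cohort scales, published analyses of this kind have used values like 2×10⁴.) |
| γ | 1/mean(&#124;M&#124;) | ADMM penalty.  The Y-update threshold is 1/γ, so this choice scales the per-iteration shrinkage to the data's magnitude; any positive value converges. |
| tol | 1e-6 | stop when relative primal residual ‖x·ι+Y+Z−M‖_F / max(1, ‖M‖_F) < tol AND the relative change of the objective < tol.  Feasibility alone is not sufficient: the residual can hit machine precision while the dual variables are still moving, so the objective-change condition is essential. |
| max_iter | 2000 | iteration cap; exhaustion returns the partial result flagged `converged=False` with a warning, never an exception. |

Initialization is Y = Z = D = 0, making the solver fully deterministic
(seed-free).  The per-iteration primal residual is recorded in
`primal_residual_trace`.

Convergence speed depends on the conditioning of the L1 problem: exact
instances (clean planted structure) converge in tens of iterations, while
fitting dense Gaussian noise through the L1 term at δ=0 has a long tail of
small threshold-crossing updates; for clustering purposes tol = 1e-4 is
ample there, since downstream co-clustering is insensitive to foreground
errors far below the block contrast.

## Checkerboard co-clustering

The exact model: partition rows into k₁ groups and columns into k₂
groups minimizing

    f(R, C) = Σ_ij ( A_ij − core[g(i), h(j)] )²,

where the core is the k₁×k₂ matrix of block centroids.  The formulation is
exact: if A is blockwise constant under some labeling, the optimum is 0.
The proximity measure is fixed to squared error, for which the optimal
core given labels is the block mean (empty blocks get centroid 0, a
convention only — they contribute no terms to the objective).

**Search.**  Maximum Block Improvement over three variable blocks — all
row labels, all column labels, the core.  Each sweep evaluates the
improvement from re-optimizing each block alone (rows decouple given
columns and core, so the row-block optimum is computed exactly per row;
ties break to the lowest group index) and commits only the block with the
largest decrease.  A group emptied by an update is repaired by moving the
worst-fitting row/column into it, keeping k₁, k₂ honest; repair happens
before the improvement comparison so the committed objective sequence is
nonincreasing by construction.

Whole-block updates can stall at configurations where no single block
alone improves.  When that happens the search switches to
maximum-improvement **single-label moves** with the core profiled out
(re-optimized implicitly): with squared error the profiled objective is
sum(A²) − Σ S²_gh/N_gh for block sums S and sizes N, so one move touches
two rows (or columns) of S and costs O(k).  The two phases alternate until
neither moves.  On exhaustively enumerable instances (6×5, k₁=k₂=2) this
combination reaches the global optimum in every best-of-20-restart run
measured, where whole-block updates alone plateau around 89%.

Initialization is uniform random labels (each group seeded with at least
one member) from an explicit seed; `best_of_restarts` (default 10 runs,
the conventional number for stochastic clustering comparisons) returns
both the best run and all runs.

**Choosing k₁, k₂.**  No principled rule exists for the block-grid
dimensions; `local_search_dims` hill-climbs the (k₁, k₂) grid scoring each
pair by best-of-restarts objective + log(mn)·k₁k₂.  The BIC-style penalty
is an invented heuristic (flagged as such): it charges each additional
block a factor proportional to the log of the data size, which suffices to
prefer (1,1) on structureless data and the planted dimensions on clean
checkerboards, but it is scale-sensitive and no claim of optimality is
made.

## Consensus

Stochastic restarts may land in different local optima, so sample
co-membership is aggregated: the consensus matrix C has entry (i,j) equal
to the fraction of runs assigning samples i and j the same column group.
Final clusters cut average-linkage hierarchical clustering of the
dissimilarity 1 − C at k groups (the extraction step is a choice, made to
match the consensus-clustering literature; the model itself does not
prescribe one).  The `stability` score is the mean within-cluster
co-assignment; ≥ 0.8 is the default convention for calling clusters
"consistent".  Selecting a single run by an external criterion (e.g. the
survival p-value of its clusters) is a reporting choice, not a method
step: the library returns all runs and the consensus and leaves selection
to the caller.

## Downstream statistics

* **differential_genes** — per-gene two-sample t-test between two sample
  groups, Welch flavor (unequal variances; robust for groups of unequal
  size), raw p-value cutoff α = 0.01 by default.  No multiple-testing
  correction is applied: the step is a screening filter whose output is
  validated on independent cohorts, and the calibration tests verify the
  advertised per-gene type-I rate, not a familywise one.  Genes with zero
  variance in both groups have no t statistic; they are excluded and
  counted in a log message.
* **intersect_signatures / filter_signature** — cross-cohort intersection
  (first signature's order preserved) and generic filtering against a
  user-supplied id list (e.g. a curated cancer-gene catalogue; none is
  bundled).
* **least_squares_classify** — nearest training-class centroid under
  summed squared per-gene differences; ties to the lowest class label.
* **km_estimate** — Kaplan-Meier product-limit curve (lifelines backend),
  returned as a callable right-continuous step function.
* **logrank_test** — two-group log-rank from first principles: at each
  distinct event time, observed minus expected events in group 1 under
  proportional allocation, with the hypergeometric variance; the statistic
  (ΣO−E)²/ΣV is referred to χ²₁.  Data with no events return (0, 1) with a
  warning.  The χ² reference is asymptotic and mildly anticonservative in
  small samples (measured ≈5.9% at 25 per group, ≈5.4% at 100 per group
  under an exponential null), which is why the calibration benchmark uses
  cohort-scale groups of 100.
* **truncate_survival** — administrative censoring at a horizon (e.g. 60
  months for 5-year survival); follow-up beyond the horizon is censored at
  it.  The horizon is a parameter, default none.

## Synthetic data: what it emulates, what it does not

`generate_fig1_toy` rebuilds the canonical 20×20 worked example: a
rank-one background of the common-vector form x·ι with x drawn uniformly
and affinely rescaled to span exactly [1, 100], plus a 5×5 foreground
block of constant value 10 at rows/columns 10–14 (1-based), no noise.
The sum is exactly rank two.  A background of the column-constant form is
the structure the common-vector model is built to remove — a generic outer
product u·vᵀ with varying v is *not* expressible as x·ι, and no method
constrained to the common-vector form could recover it, so planting the
compatible form is the meaningful benchmark.  (Recovery of generic
low-rank backgrounds is the multi-condition model's job, and is exercised
separately with `common_background=False`.)

`generate_planted` generalizes this: balanced random row/column partitions
into k₁×k₂ groups, a full matrix of block effects, optional generic
low-rank background, i.i.d. Gaussian noise, ground-truth labels returned.
Defaults mirror the toy's contrast (one block of effect 10).

What passing the synthetic benchmarks does **not** show: real cohorts have
correlated genes, batch effects, heavy-tailed noise, unbalanced subtype
sizes, and backgrounds that are only approximately column-constant after
normalization.  Exact recovery and ARI 1.0 on planted instances
demonstrate correctness of the optimization and the pipeline plumbing,
not expected field performance.  Reproducing published cohort-level
results (specific cluster memberships, 128/144-gene signatures, cohort
survival p-values, LOOCV accuracies) requires the original consortium/GEO
downloads plus run-selection choices and is explicitly out of scope here;
the property-based suites are the acceptance surface for those stages.
Normalization of real data is likewise left to the user: no particular
dialect is bundled or claimed.

## Benchmark problem sizes and tolerances

Chosen as the package's own test design:

* worked example: 20×20, δ=0, tol 1e-10 — recovery asserted to 1e-5
  entrywise (measured ~1e-9);
* solver-vs-generic-convex-solver comparison: 10 instances of 8×10 at
  δ ∈ {0, 0.5}, agreement of ‖Y‖₁ to 1e-4 relative (scipy trust-constr on
  the epigraph reformulation as the independent solver; duality-gap and
  subgradient certificates for the nuclear-norm program and the proximal
  operators);
* co-clustering vs exhaustive enumeration: 50 instances of 6×5 with
  k₁=k₂=2 (2¹¹ labelings each), best-of-20 restarts, ≥95% required;
* pipeline recovery: 40×40, one planted block of effect 10 on a rank-one
  common background; ARI 1.0 required noiseless, mean ARI ≥ 0.9 at noise
  sd 1 over 20 seeds (the decomposition there runs at tol 1e-4 — see the
  convergence note above);
* calibration: 10,000 null genes at α = 0.01 (band ±0.3%); 2000 log-rank
  replicates under an exponential null with 100 subjects per group (band
  5% ± 1%).

## Known limitations

* The common-vector background cannot represent sample-specific scaling
  (columns proportional rather than equal); apply per-sample normalization
  first or use the multi-condition model.
* δ is in absolute Frobenius units and must be chosen per dataset.
* The MBI search is a local method; guarantees are empirical (restarts +
  refinement), not global.
* The k-selection penalty in `local_search_dims` is heuristic.
* d-way tensor co-clustering (d > 2), missing values, out-of-core
  matrices, and Cox-model survival analysis are out of scope.
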