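# Methods

## Problem setting and model

Two single-cell datasets measure overlapping but non-identical feature
panels on (potentially) the same kind of biological material. Writing
`X = (X_share X_dist)` and `Y = (Y_share Y_dist)`, the goal is an
injective map Π from the cells of the smaller dataset X into the cells of
Y such that matched cells share a biological state. Conceptually the
pipeline targets a single optimization problem,

    maximize   Tr(Aᵀ Xᵀ Π H Y B)
    subject to Π ∈ S(n, m),  Aᵀ Xᵀ X A = I,  Bᵀ Yᵀ Y B = I,

with `H` the centering matrix and `S(n, m)` the set of selection/
permutation matrices: for fixed Π the optimal (A, B) are the top-k CCA
loadings of the aligned pair, and for fixed (A, B) the optimal Π solves a
rectangular linear assignment problem (LAP). The pipeline is an
alternating, warm-started approximation to this objective — the unified
problem is a documented contract, not a separately coded solver.

## Pipeline stages

**Denoising.** The stacked shared blocks `[X_share; Y_share]` are
truncated to rank `n_components_ovlp` by SVD; both reconstructions share
right singular vectors and singular values. Default rank 10, clipped to
`p_share` with a warning.

**Distances.** Pearson cross-distance `1 − cor(row_i, row_j)` (entries in
[0, 2]); rows with zero variance get distance 1 (neutral) with a logged
count rather than an error, since a single flat cell should not abort a
large run. A Laplacian-kernel option `1 − exp(−‖·‖₁/h)` is provided; the
default bandwidth is the median L1 distance over a seeded subsample of at
most 1000 row pairs.

**Assignment.** Dense instances are solved by
`scipy.optimize.linear_sum_assignment`, sparsified instances by
`scipy.sparse.csgraph.min_weight_full_bipartite_matching`. Sparsification
keeps the `sparsity` smallest-distance candidates per X row (default
5000; a no-op when it reaches n_y). If the sparse bipartite graph admits
no perfect matching, the deficient rows are augmented with fallback
entries costing one more than the largest kept distance, and the
augmentation is logged; stored sparse costs carry a +1 shift so explicit
zeros are never lost (a constant per-entry shift leaves the argmin
unchanged). Among equal-cost optima the dense solver's output is made
canonical by cost-neutral transpositions toward the lexicographically
smallest pair list, so results are reproducible across platforms.

**CCA.** Solved by whitening both within-set covariances (symmetric
eigendecomposition) and taking the SVD of the whitened cross-covariance —
deterministic and free of iterative convergence issues. A ridge `λI` is
added to each covariance; the default is trace-scaled `1e-6`
(`1e-6 · tr(S)/p`), which keeps rank-deficient panels solvable while
perturbing correlations only at the ~1e-6 level. `ridge=0` raises an
instructive error on rank-deficient input. Canonical correlations are
clipped to [0, 1] and returned in descending order.

**Interpolation and selection.** λ grid {0, 0.1, …, 1}. For every λ the
assignment is re-solved and CCA re-fitted on the aligned pair; the
quality proxy is the mean of the top-k (k = 10, clipped to availability)
sample canonical correlations. Re-fitting per λ follows the literal
selection recipe; ties go to the smaller λ (the more conservative
shared-feature matching). The quality proxy is only informative when the
number of aligned pairs comfortably exceeds the feature count — with tens
of cells and top-k ≈ p the CCA overfits any alignment and the proxy
saturates; the test fixtures therefore use n ≥ 150.

**Batching.** When `n_x > n_y`, or simply on request, X is randomly
segmented into `n_batch` equal-sized batches (seeded shuffle). Each batch
is matched against the *full* Y dataset: this preserves per-batch global
optimality, at the cost that a Y cell may serve several X cells across
batches (logged). An optional strict mode removes matched Y cells between
batches instead. The default is non-strict because per-batch optimality
is the property the assignment formulation actually guarantees.

## Quality control

**Matchability test.** B replicates (default 20; calibration experiments
use 99) flip each row of X and of Y independently with probability
`p_flip` (default 0.2), re-run the matcher, and record the mean top-k
canonical correlation after alignment. The p-value is the proportion of
background values ≥ the observed statistic, computed by default with the
conservative `(#{≥}+1)/(B+1)` convention so a finite-B p-value is never
exactly zero (the plain proportion is available via a flag). Replicates
on which the matcher fails are dropped with a warning; more than 20%
dropped is a hard error. A fast mode restricts each replicate to the
shared-feature initial matching; it is used where B·trials is large
(calibration suites) since the background is driven by the flip, not by
the refinement stage. Note a structural property of the test: power
comes from cells being quasi-unique. If many interchangeable cells exist
per population, a flipped X cell can find a flipped Y cell of the same
population and the background stays high; the test then measures
matchability at the resolution of individual cells, not of populations.

**Jointly regularized filtering.** The regularized k-means objective

    ½ Σᵢ (‖Xᵢ−μ_{z_x,i}‖² + ‖Yᵢ−ν_{z_y,i}‖²)
    + log((1−ρ)/(ρ/(K−1))) Σᵢ (1{z_x,i≠z_⋆,i} + 1{z_y,i≠z_⋆,i})

is minimized by warm-started block coordinate descent (default 20
iterations): centroid updates are per-label means; the label update is
exact per pair, enumerating the K global-label hypotheses with the best
individual labels computed in closed form (ties resolved toward the
smallest label index, matching a lexicographic exhaustive search). The
warm start averages the two canonical score matrices and runs seeded
k-means on the top-K left singular vectors. Empty clusters retain their
previous centroid (deterministic, keeps the objective monotone); the
objective value is recorded at every half-step and is non-increasing by
construction. Valid range 0 < ρ < 1−1/K; ρ → 1−1/K gives independent
per-dataset k-means, ρ → 0 forces `z_⋆ = z_x = z_y`. Defaults K = 10,
ρ = 0.2. Pairs with `z_x ≠ z_y` at convergence are discarded.

## Embedding and transfer

CCA scores of the filtered aligned pair, z-scored per component within
each dataset, are the joint embedding (default 20 components, clipped to
the available rank). For ≥3 row-aligned datasets, generalized CCA in the
MAXVAR formulation: common scores are the top left singular vectors of
the concatenated orthonormal column bases; per-dataset scores are their
projections onto each dataset's column space, which for two datasets
spans the ordinary CCA score subspace. Label transfer takes the majority
label among the k nearest Y cells (k = 5) under the selected interpolated
distance, breaking ties by the nearest tied label.

## Benchmark metrics

Matching accuracy divides correct same-type pairs by *all* X cells, so
filtering trades numerator against proportion transparently; the
matched-only denominator is exported alongside because either reading is
defensible. Structure alignment is the per-cell Pearson correlation
between full-feature and embedding distance rows, averaged (degenerate
constant rows skipped with a warning). Silhouette/ARI F1 are harmonic
means of a mixing term (1 − score on the dataset label) and a
preservation term (score on the type label), silhouettes normalized by
(s+1)/2 and ARI clipped at 0 since the harmonic mean needs non-negative
parts. Note that perfectly mixed datasets yield silhouette ≈ 0, i.e. a
mixing term of ≈ 0.5, so the practical ceiling of the silhouette F1 is
about 2/3. Average mixing is the mean over clusters of the median over
coordinates of 1 − KS statistic between the two datasets. The error
avoidance score is the literal √(a/b) over cells of a deliberately
deleted type (a = still matched after QC, b = total); because the printed
formula *increases* when forced matches survive, an `inverted` option
reporting 1 − √(a/b) is provided, and neither direction is asserted as
ground truth.

## Synthetic data generator

A linear-Gaussian generative model stands in for kinetic simulators:
population centroids are drawn in a latent space (dimension 10, scale =
`separation`, default 2.0), each cell adds unit within-population spread,
and the observed panels are linear readouts of the latent state — one
common loading matrix for the shared block, modality-specific loadings
for the distinct blocks — plus per-feature Gaussian noise (`noise_sd`,
default 0.5) and a systematic per-feature modality shift (default 0.3,
removed by per-dataset z-scoring). Every X cell has a Y twin observing
the same latent state, so a perfect matching exists and accuracy is
interpretable; Y carries additional twin-less cells. Defaults follow the
benchmark design: 20 populations, 20 shared + 20/20 distinct features.
The acceptance experiment uses 1,000 × 2,000 cells and three seeds — a
desk-scale size at which per-population counts (~50 in X) make
population-level accuracy stable.

What the generator does *not* emulate: count noise and dropout, nonlinear
feature responses, population-specific covariance shapes, batch effects
beyond a mean shift, and cells of types absent from one side (available
only through the drop-types perturbation). Passing tests therefore show
that the pipeline recovers a planted linear-Gaussian correspondence, not
that it resolves every pathology of real multimodal panels.

## Numerical choices and limitations

All randomness flows from user-supplied integer seeds through
`numpy.random.default_rng`/`SeedSequence`. Zero-variance feature columns
are centered only (warned); NaN values are rejected at load with row and
column coordinates, never imputed, because correlation-based distances
would silently absorb imputation bias. Equal-cost assignment ties are
canonicalized only on dense problems up to 4·10⁶ entries (the sparse
solver output is already deterministic). The interpolation grid re-solves
one LAP per λ, which dominates runtime on large instances; sparsification
bounds this cost. Known limitations: the matchability test loses power on
coarsely clustered data (see above); the filter assumes K is a reasonable
upper bound on the joint cluster structure; and matching more than two
datasets is supported only pairwise, with gCCA providing the shared
embedding afterwards.
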