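# mario — cell matching across single-cell datasets with partially shared panels

`mario` matches individual cells one-to-one across two single-cell
datasets (e.g. CyTOF ↔ CITE-seq, CODEX ↔ CITE-seq) whose antibody panels
overlap only partially, then integrates the matched cells into a joint
low-dimensional embedding. It is aimed at computational biologists who
need cross-modality cell pairing with statistical quality control rather
than greedy mutual-nearest-neighbor heuristics.

## Method

Given cell-by-feature matrices `X ∈ R^{n_x×(p_share+p_x)}` and
`Y ∈ R^{n_y×(p_share+p_y)}` (n_x ≤ n_y) written as concatenations of a
shared and a distinct block, the pipeline estimates an injective matching
Π (a binary n_x×n_y matrix with unit row sums) in three stages:

1. **Initial matching on shared features.** The stacked shared blocks are
   jointly denoised by a truncated SVD (rank `n_components_ovlp`, default
   10) and the rectangular linear assignment problem
   `Π̂_share = argmin_Π ⟨Π, D_share⟩` is solved globally, where
   `(D_share)_{ii'} = 1 − cor(X̂_share,i , Ŷ_share,i')` is the Pearson
   cross-distance (a Laplacian-kernel distance is available).
2. **Refinement with distinct features.** Aligning Y to X via Π̂_share
   allows fitting CCA on the full feature matrices; a refined distance
   `D_all` is computed between the canonical scores of all cells
   (`n_components_all`, default 20) and solved the same way.
3. **Interpolation.** For each λ on a grid, the convex combination
   `D_λ = (1−λ)D_share + λD_all` is solved; the mean of the top-k sample
   canonical correlations after alignment (k = 10) scores each candidate
   and the best λ is kept (ties favor the conservative λ = 0).

Two quality-control steps guard the result. The **matchability test**
rebuilds the matching on B sign-flipped replicates (each cell row
multiplied by −1 with probability `p_flip` = 0.2), which destroys
cross-dataset correlation while preserving within-dataset covariance, and
reports the proportion of background statistics exceeding the observed
one. **Jointly regularized filtering** minimizes a k-means objective in
which per-dataset labels `z_x, z_y` are tied to a global label `z_⋆`
through the penalty `log((1−ρ)/(ρ/(K−1)))·(1{z_x≠z_⋆}+1{z_y≠z_⋆})`;
matched pairs whose two labels disagree at the optimum are discarded.
Surviving pairs are embedded by CCA (generalized CCA, MAXVAR variant, for
three or more datasets), and labels can be transferred across datasets by
k-nearest-neighbor vote on `D_λ̂`.

## Worked example

`examples/01_match_synthetic_pair.py` generates a paired two-modality
dataset (20 latent cell populations; 60 features of which 20 are shared
and 20 distinct per modality), matches it, and prints:

```
selected lambda      : 0.0   (0 = shared-feature matching only)
quality proxy        : 0.952 (mean of top-10 canonical correlations)
population accuracy  : 0.981 (matched cell has the correct population)
exact-twin recovery  : 0.816 (matched cell is the true twin)
```

98.1% of cells are paired to a cell of their own population; 81.6% to
their exact generative twin (cells of one population are nearly
interchangeable partners, so twin recovery is the stricter number). The
other examples demonstrate quality control, joint embedding with label
transfer, and the perturbation benchmarks.

The same workflow is available from the shell:

```bash
mario simulate --seed 1 --out fixtures/
mario run --x fixtures/X.csv --y fixtures/Y.csv --out results/
```

`mario run` writes `matching.csv`, `qc_report.json`, per-dataset
embedding CSVs and a `manifest.json` with config, seeds and input hashes;
it aborts before embedding when the matchability test fails (override
with `--force`).

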