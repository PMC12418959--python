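# mlmf — multi-layer matrix factorization for multi-omics cancer subtyping

`mlmf` identifies disease subtypes from several omics modalities at once —
mRNA expression, DNA methylation, miRNA, CNV — including cohorts where some
patients are missing entire modalities.  It is aimed at computational
biologists who have per-modality feature × sample matrices and want a single
latent embedding of all patients plus cluster (subtype) labels.

## The model

Each omics view `X⁽ᵛ⁾ ∈ R^{D_v × N_v}` is factorized through a stack of
semi-nonnegative layers,

    X⁽ᵛ⁾ ≈ Z₁⁽ᵛ⁾ Z₂⁽ᵛ⁾ … Z_m⁽ᵛ⁾ H_m⁽ᵛ⁾ ,   H_m⁽ᵛ⁾ ≥ 0 ,

where the bases `Zᵢ` may be mixed-sign and only the deepest representation
is nonnegative.  Views need not observe the same patients: a binary
indicator matrix `G⁽ᵛ⁾` maps the intact (union) patient set onto each
view's observed columns, and all views are fused into one consensus
embedding `H ∈ R^{d × N}` by minimizing

    Σ_v ‖X⁽ᵛ⁾ − Z₁…Z_m H_m⁽ᵛ⁾‖²_F
        + λ₁ Σ_j ‖(H_m⁽ᵛ⁾)·ⱼ‖₁²  +  λ₂ ‖H_m⁽ᵛ⁾ − H G⁽ᵛ⁾‖²_F .

Two solvers are provided: a **linear** coordinate-descent solver
(pseudoinverse basis updates, a sign-safe multiplicative update for
`H_m`, and a closed-form consensus update) and a **nonlinear** solver that
composes the layers through an elementwise activation (relu, sigmoid or
tanh) and fits by projected gradient descent with a monotone backtracking
line search.  Subtypes are assigned by spectral clustering of the consensus
embedding: a k-nearest-neighbour Gaussian affinity graph
`W_ij = exp(−‖h_i − h_j‖² / t)` followed by the normalized-Laplacian
(Ng–Jordan–Weiss) recipe.

## Worked example

Generate a synthetic three-view cohort with four planted subtypes in which
half of the first view's patients are missing, fit the linear model, and
cluster:

```python
from mlmf import MLMF, SimulationConfig, generate_dataset, adjusted_rand_index

dataset, truth = generate_dataset(SimulationConfig(theta=(0.5, 0.0, 0.0), seed=7))
model = MLMF(dataset, n_clusters=4, seed=7)
result = model.fit()
print(result.summary())
subtypes = result.cluster()
print("estimated k:", result.estimate_num_clusters())
print("ARI vs truth:", round(adjusted_rand_index(subtypes.labels, truth.labels), 3))
```

This prints:

```
Multi-Layer Matrix Factorization Results
================================================
mode:             linear
views:            3
intact samples:   200
layer dims:       [50, 4]
lambda1/lambda2:  1 / 1
sweeps run:       50 (max 50)
converged:        False (tol 0.0001)
final objective:  34559
------------------------------------------------
view      D_v    N_v   rel. recon. error
omics0     100    100   0.2842
omics1     100    200   0.2718
omics2     100    200   0.2620
estimated k: 4
ARI vs truth: 1.0
```

The summary shows the fitted configuration and, per view, its size and the
relative Frobenius reconstruction error (about 0.27 here, consistent with
the simulated noise level).  The first view retains only 100 of the 200
patients, yet the eigengap heuristic recovers the planted number of
subtypes and the labels match the ground truth exactly (adjusted Rand
index 1.0) because the two complete views cover every patient.

The same pipeline is available from the shell:

```sh
mlmf simulate --config sim.yaml --out data/
mlmf fit --mode linear --omics data/omics0.csv --omics data/omics1.csv \
         --omics data/omics2.csv --k 4 --out fit/
mlmf cluster --consensus fit/consensus.csv --k auto --out labels.csv
mlmf evaluate --labels labels.csv --truth data/truth_labels.csv
```

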