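# Methods

## Model

`mlmf` fits one factor stack per omics view and couples the stacks through
a shared consensus embedding.  For view `v` with feature matrix
`X⁽ᵛ⁾ ∈ R^{D_v × N_v}` the linear model is the multi-layer
semi-nonnegative factorization

    X⁽ᵛ⁾ ≈ Z₁⁽ᵛ⁾ … Z_m⁽ᵛ⁾ H_m⁽ᵛ⁾,   H_m⁽ᵛ⁾ ≥ 0,

with layer sizes `d₁ > … > d_m`.  Only the deepest representation is
constrained nonnegative (semi-NMF): omics matrices after z-scoring are
mixed-sign, so the bases must be free to carry sign while the deepest
layer stays interpretable as nonnegative part intensities.  The nonlinear
variant inserts an elementwise activation between layers,
`X ≈ Z₁ f(Z₂ f(… f(Z_m H_m)))`, leaving the outermost layer linear so the
reconstruction can reach arbitrary real values.

Views may observe different patient subsets.  The intact sample set is the
union of all view samples (ordered lexicographically, which is
deterministic across runs and input orderings); each view carries a binary
indicator `G⁽ᵛ⁾ ∈ {0,1}^{N × N_v}` with `G[i, j] = 1` iff intact position
`i` is the view's j-th column.  Internally the consensus is stored as
`H ∈ R^{d × N}` (columns are patients) so that `H G⁽ᵛ⁾` selects the view's
observed columns and every update below is dimensionally consistent.

The joint objective, per view,

    ‖X − Z₁…Z_m H_m‖²_F + λ₁ Σ_j ‖(H_m)·ⱼ‖₁² + λ₂ ‖H_m − H G‖²_F,

combines reconstruction, a column-sparsity penalty (equal to
`Tr(H_m H_mᵀ E)` with `E` the all-ones matrix — both forms are computed and
cross-checked in the tests), and the consensus coupling.  Defaults
λ₁ = λ₂ = 1, at most 50 sweeps, relative objective tolerance 1e-4.

## Linear solver

Coordinate descent; each step is individually non-increasing, so the
per-sweep loss trace descends monotonically (asserted in the tests with
1e-9 relative slack for floating-point noise):

- **Bases** `Zᵢ ← φ⁺ X H̃ᵢ⁺` with `φ = Z₁…Zᵢ₋₁`, `H̃ᵢ = Zᵢ₊₁…Z_m H_m` —
  the minimum-norm exact least-squares minimizer with everything else
  fixed.
- **Deepest representation**: with `A = H_m`, `Ψ = Z₁…Z_m`,
  `B = ΨᵀX + λ₂ H G`, `C = ΨᵀΨ + λ₁E + λ₂I`, the sign-safe multiplicative
  step `A ← A ⊙ sqrt((B⁺ + C⁻A) / (B⁻ + C⁺A + ε))` using the positive /
  negative parts `M± = (|M| ± M)/2`.  This is the standard
  auxiliary-function-monotone rule for the quadratic
  `tr(AᵀCA) − 2tr(BᵀA)` under `A ≥ 0`.  ε = 1e-12 guards the denominator;
  zero entries of `A` are preserved by construction.
- **Intermediate representations** `Hᵢ (i < m)` are refreshed by the
  analogous multiplicative rule toward the least-squares fit of
  `X ≈ Ψᵢ Hᵢ`.  They expose the per-depth feature hierarchy; the global
  objective depends only on the bases and the deepest layer, so this step
  cannot increase the loss.
- **Consensus** `H = [Σ_v H_m⁽ᵛ⁾ G⁽ᵛ⁾ᵀ][Σ_v G⁽ᵛ⁾G⁽ᵛ⁾ᵀ]⁻¹` — the exact
  minimizer of the coupling term.  The Gram sum is diagonal with entry j
  equal to the number of views observing patient j, hence invertible iff
  every patient is observed somewhere (validated, with a named-sample
  error otherwise).

## Nonlinear solver

The objective is a pure composition of the bases and `H_m`; hidden
representations are cached values `f(Zᵢ Hᵢ)` and therefore implicit
functions of the deeper factors, not free variables.  Gradients are
obtained by the usual backward recursion
`∂L/∂Hᵢ = Zᵢᵀ[∂L/∂Hᵢ₋₁ ⊙ f′(ZᵢHᵢ)]` seeded with the outermost residual
`2(X̂ − X)`; at the deepest layer the penalty gradients
`2λ₁E H_m + 2λ₂(H_m − HG)` are added, and the consensus gradient is
`2λ₂ Σ_v (H G Gᵀ − H_m Gᵀ)`, which vanishes exactly at the linear solver's
closed form.  All analytic gradients are verified against central finite
differences (h = 1e-6, relative error < 1e-5) across depths 1–3 and all
three activations.

Each sweep takes one line-searched gradient step per parameter block
(`H_m`, every `Zᵢ`, then `H`).  The "adaptive step size" is a monotone
backtracking search: starting from the block's current step (initially
1e-2) the step is halved, up to 30 times, until the full objective does
not increase; an accepted full step grows the next step by 1.2.  `H_m` is
projected onto the nonnegative orthant before evaluation, so feasibility
and exact monotonicity of the trace hold simultaneously.  If every block
of a sweep exhausts its backtracks the fit stops with a warning rather
than an error.  Default activation is relu; sigmoid and tanh are
selectable (the choice is a genuinely open modelling question — nothing in
the formulation pins f down — so it is exposed as a parameter).

## Initialization and frame alignment

Factors are pretrained layer-wise: truncated SVD `X ≈ U(SVᵀ)` with signs
fixed so each left singular vector's largest-magnitude entry is positive,
then recursion on the representation.  Nonnegativity is imposed by
shifting each representation row by its minimum rather than clipping:
clipping zeroes roughly half of every latent coordinate and — because the
multiplicative rule preserves zeros — freezes that loss permanently,
which measurably destroys downstream cluster recovery; a per-row shift is
a translation that keeps the sample geometry intact.

A subtlety of per-view pretraining is that each view's SVD orders and
orients latent components by its own spectrum, so the same latent axis can
appear as a different (or flipped) coordinate in different views, and
averaging unaligned frames into a consensus cancels structure.  After
pretraining, the deepest-layer frames are therefore aligned to the view
observing the most samples: the signed row permutation of `H_m` maximizing
row-wise correlation with the reference (centered, over shared samples,
solved by linear assignment) is applied and its inverse absorbed into
`Z_m`, leaving the reconstruction unchanged.  Views sharing fewer than
three samples with the reference are left as-is.  The whole initialization
is deterministic; the solver seed only controls k-means restarts in the
clustering stage.

Default layer sizes are `[min(100, ⌊min_v min(D_v, N_v)/2⌋], d]` with the
latent dimension `d` equal to the requested cluster count when known (else
20): a wide first layer to absorb modality-specific structure and a narrow
deepest layer matched to the number of expected subtypes.

## Subtyping

Patients are clustered on the consensus embedding columns.  The affinity
graph uses symmetric-OR k-nearest neighbours (an edge survives if either
endpoint lists the other), k = min(15, N − 1) by default, with Gaussian
weights `exp(−d²/t)`; `t` defaults to the mean squared distance over
retained neighbour pairs (self-tuning, scale-free).  Spectral embedding
follows Ng–Jordan–Weiss: the k smallest eigenvectors of
`L = I − D^{−1/2}WD^{−1/2}`, rows normalized to unit length, clustered by
k-means (k-means++ with 50 restarts, best inertia kept, seeded).  Labels
are relabeled so cluster 0 is the largest (ties broken by first
occurrence), making outputs comparable across runs.  The cluster count can
be estimated by the eigengap heuristic (argmax of λ_{k+1} − λ_k for
k = 2…k_max); a warning flags estimates whose winning gap is below twice
the median gap.

## Synthetic data

The generator mirrors the model's own data mechanism: k cluster centroids
in latent dimension d (default d = k) drawn from a standard Gaussian and
rescaled so their minimum pairwise distance equals the separation
parameter; each patient's latent column is its centroid plus unit Gaussian
jitter; view v observes `L⁽ᵛ⁾ latent + noise`, with loadings
`L⁽ᵛ⁾ ∈ R^{D_v × d}` of i.i.d. N(0, 1/d) entries and i.i.d. Gaussian
observation noise.  Missingness removes whole sample columns from a masked
view — `⌊θ N_v⌋` patients drawn uniformly without replacement — while
designated complete views are untouched, so every patient stays observed
somewhere (validated before any mutation).

Reference conditions, used as the defaults and throughout the test
battery: N = 200 patients, V = 3 views of D = 100 features, k = 4 clusters,
separation 5 against unit jitter, observation noise sd 0.5, and masking
rates θ ∈ {0.1, 0.3, 0.5, 0.7} applied to the first view with the other
views complete.  D = 100 and d = k are the package's own choices of a
realistic post-feature-selection panel size and a minimal sufficient
latent dimension.  Monotone-descent checks run at a smaller
N = 60 / V = 2 / D = (40, 30) scale so that 20 replicate fits per solver
stay fast; the solver settings there are exactly the defaults.

What the generator does **not** emulate: realistic marginal distributions
(counts, beta values, heavy tails), feature–feature correlation beyond the
shared latent structure, batch effects, or partially missing values within
an observed patient.  Passing tests therefore demonstrate correctness of
the optimization and the recoverability of planted low-rank cluster
structure under modality dropout — not performance on real cohorts, which
additionally depends on preprocessing and on how well a linear latent
model approximates each modality.

## Numerical choices and edge cases

- Population (1/N) standard deviation for z-scoring; zero-variance
  features are dropped with a warning (never imputed), and an all-constant
  view is an error.
- `"NA"` or empty cells in input tables are parse errors with the
  offending feature/sample named: missing data means absent columns, not
  holes.
- Pseudoinverses use numpy defaults; rank-deficient basis updates return
  the minimum-norm solution.
- kNN ties are broken by stable index order; duplicate points are legal.
- Multiplicative-update denominators carry ε = 1e-12; numerators do not,
  so structural zeros are preserved (this is intentional model sparsity).
- The eigengap scan requires k_max < N; isolated graph vertices raise an
  error suggesting a larger neighbour count.

## Known limitations

- With the penalties active (λ₁, λ₂ > 0) the linear solver's zero-locking
  multiplicative rule converges to sparser stationary points than the
  projected-gradient nonlinear solver run with an identity activation, so
  their final objectives need not coincide; with the penalties off the two
  agree to a fraction of a percent.  The two solvers are different
  estimators of the same model, not interchangeable optimizers.
- λ₁ and λ₂ are not selected automatically; both default to 1.
- The consensus update requires every patient in at least one view;
  patients absent everywhere must be dropped upstream.
- Dense linear algebra throughout: cohorts beyond a few thousand patients
  per view would need sparse or randomized variants.
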