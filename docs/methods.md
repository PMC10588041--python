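# Methods

## The model

`fibrenmf` decomposes a nonnegative sample x feature frequency matrix
`X` (n samples, p = 101 aggregated functional traits, AFTs) into a small
number k of *functional profiles*:

    X  ~  W H,    W >= 0 (n x k),   H >= 0 (k x p),   F H^T <= 0,

by minimizing

    || (X - W H) D^-1 ||_F^2  +  alpha ( ||W||_F^2 + ||H D^-1||_{1,2}^2 )

* `D` is the diagonal matrix of column l2 norms of `X`, so that every AFT
  enters the fit on a comparable scale regardless of its absolute abundance.
  Zero-norm columns are dropped before fitting and reinserted as zero columns
  of `H` (their inverse scale is undefined).
* `||A||_{1,2}^2` is the sum over feature columns of the squared l1 norm
  across profiles. On nonnegative `H` this is the quadratic form
  `sum_j (1' h_j)^2`; it penalizes an AFT loading on many profiles at once,
  i.e. pushes each AFT toward a small number of profiles. The alternative
  reading (row-wise l1) would not have that effect, which is why the
  column-wise orientation was adopted.
* `||W||_F^2` is a plain ridge on the weights, evening out profile weights
  within a sample.
* `F` (155 x 101) encodes *pathway completeness*: linear inequalities such as
  `h_consumer - sum(h_producers) <= 0` for each intracellular metabolite,
  forcing any profile to carry whole intracellular chains between
  extracellular compounds rather than isolated enzymes.

### Optimization

Block coordinate descent between two convex subproblems, each solved to its
global optimum:

* **W step** — each sample row is an independent nonnegative ridge
  least-squares problem. With k <= ~12 variables the exact solution is found
  by enumerating active sets and checking the KKT conditions, vectorized over
  samples (`_solvers.nnls_gram_multi`).
* **H step** — the l1,2 penalty is column-separable, but the rows of `F`
  couple the feature columns of `H` within each profile, so the update is one
  convex QP over all k*p entries. It is solved exactly through its Lagrangian
  dual: for constraints `C x <= 0` and positive-definite block-diagonal `P`,
  the dual is itself a nonnegative least-squares problem, handled by a
  warm-startable block-pivoting active-set iteration (Portugal–Júdice–Vicente
  with Murty's finite-termination safeguard). When the unconstrained
  column-wise solution already satisfies `F H^T <= 0` it is accepted directly
  (zero multipliers satisfy the KKT system).

Because each half-step is an exact convex solve, the objective trace is
non-increasing (asserted to 1e-8 relative tolerance in tests). Tolerances:
QP/KKT 1e-9; feasibility contract on any returned `H` is
`max(F H^T) <= 1e-6`.

Initialization draws `W` and the *scaled* profiles `G = H D^-1` elementwise
from Uniform(0,1), rescaled so `mean(W G)` matches `mean(X D^-1)`; drawing in
the scaled space makes the fit exactly equivariant to per-feature rescaling
(at alpha = 0, without `F`). The initial `H` is projected row-wise onto
`{h >= 0, F h <= 0}` (nearest-point QP) so that the very first H step is
already a descent step. The fit runs `n_restarts = 5` seeded restarts
(default) and keeps the lowest objective, ties to the lowest restart index;
stopping at relative objective change < 1e-6 or 500 iterations. A final
W half-step after convergence makes the returned `W` the exact regression of
`X` on the returned `H`, so projecting the training matrix reproduces it.

Profiles are returned in a canonical order of decreasing average contribution
`mean(W_i) * sum_j H_ij` (profile 1 = dominant); the order is invariant to
how scale is split between `W` and `H`.

### Scale conventions

`W H` is invariant under per-profile rescaling, so weight-balance statistics
are only meaningful under a fixed convention.
`nmf.normalize_profile_scale(W, H)` moves the scale so each `H` row sums to
one (profiles as frequency vectors); apply it before computing
`W* = W2/(W1+W2)` or ternary coordinates.

### Downstream solves

* **Projection** of external samples: the W step with `H` fixed, reusing the
  *training* `D` (the profiles' column scale is defined relative to it).
* **Feature affectation** (genomes, genera, transcripts): one H step with `W`
  fixed, with `D` recomputed from the target matrix's own columns; `F` is
  supplied for transcript targets (pathway semantics applies) and omitted for
  taxonomic ones.
* **Relative reconstruction error** is per-sample `||x_i - (WH)_i|| / ||x_i||`,
  unscaled (no `D`).

## Hyperparameter selection

Triple criterion over a (k, alpha) grid:

1. *Internal error* — mean per-sample relative error of a full fit.
2. *Bi-cross-validation* — Gabriel scheme: rows and columns are split into
   folds; for each held-out block X22, factors are fitted on X11, held-out
   column profiles inferred from X12 (fixed W), held-out row weights from X21
   (fixed H), and X22 predicted through the shared k-space. `F` rows are
   restricted to those fully supported on the retained columns.
3. *Stability* — mean permutation-matched cosine similarity between profile
   matrices refitted on random 80% row subsamples (Hungarian matching).

Decision rule: among points with stability >= 0.9, minimize bi-CV error with
a one-standard-error-style parsimony margin — errors within 0.5% (relative)
of the minimum count as tied and resolve to the smallest k, then the largest
alpha. The margin exists because past the true rank the bi-CV curve is
essentially flat and the literal argmin flips between k and k+1 on noise-level
differences. Selection-time fits use a reduced budget (2 restarts, 120
iterations, rel_tol 1e-5 by default) since only the ranking matters; these
knobs sit on `SelectionGrid`.

## Dysbiosis diagnostics

Pairwise Bray–Curtis dissimilarity `BC(u,v) = sum|u_j - v_j| / sum(u_j + v_j)`
(scipy's implementation). The dysbiosis index of a sample is the *median* BC
distance to a reference sample set, excluding reference samples from the same
individual; the reference rule is pluggable (the cohort-style rule selects
non-IBD samples past week 20; synthetic runs use the generator's healthy
group). The dysbiotic threshold is the 0.9 empirical quantile (linear
interpolation, numpy's default convention) of DI over healthy samples;
samples strictly above it are flagged. If exclusions empty a sample's
reference, its DI is NaN and it is never flagged.

## Profile statistics

* Average profile contribution to feature j: `Wbar_i H_ij / Xbar_j`, with
  residual `1 - sum_i`; zero-mean features are excluded (NaN) with a warning.
  Contribution + residual = 1 holds by construction for every reported
  feature.
* `W* = W2/(W1+W2)` per sample (NaN-flagged when W1+W2 = 0); ternary
  coordinates normalize a chosen profile triple to sum 1.
* Differential contribution shift between two groups: first-timepoint
  deduplication per individual, per-feature Welch t-test (robust to unequal
  group variances), Benjamini–Hochberg FDR < 0.05,
  then ranking of surviving features by the l2 norm of the difference of
  their per-profile contribution vectors; truncation to the top 20. A
  `normalize_l1` flag switches to per-sample l1-normalized W and X (the
  module-level convention); a `test_on_relative` flag controls whether the
  t-test runs on closed compositions (default off).

## Synthetic data generator

The generator plants everything the analysis assumes, so every stage has a
known ground truth:

* **Profiles** — sparse Gamma draws, biased toward distinct network slices
  (profile 1 toward GH/PL cleavage, 2 toward core fermentation KOs, 3 toward
  the alternative fucose/propionate/sulfur/ED routes, 4 toward
  methanogenesis/WL), then projected onto `{h >= 0, F h <= 0}` by
  nearest-point QP and row-normalized. Feasibility is asserted at 1e-8.
* **Weights** — three groups mirroring the reported regime: healthy
  (W* ~ Normal(0.20, 0.03), clipped), dysbiotic (W* ~ Normal(0.35, 0.15) —
  higher mean *and* dispersion), Crohn's-like (profile-3 share 0.25 of the
  sample total vs 0.03/0.06 elsewhere). Profile 4 follows a carrier model
  (share ~0.05 in a 40% carrier subset, a 0.002 trace elsewhere) because
  methanogen carriage in real guts is bimodal; a uniform tiny share would
  make the fourth profile unidentifiable in a way real data is not. Sample
  totals are lognormal with CV 0.2. A fraction of individuals contributes a
  second timepoint so deduplication logic is exercised.
* **Counts** — `X = (W H) * E` with `E` i.i.d. lognormal, mean 1, CV
  `noise_cv` (default 0.2). Multiplicative lognormal noise was chosen over
  Poisson at the AFT level because the data model is relative frequencies,
  not integer counts; a Poisson layer is available in the gene table
  generator for raw counts.
* **Gene tables** — each AFT's per-sample mass is split over member genes
  (Dirichlet shares); a configured fraction of AFT pairs routes mass through
  a dual-annotated gene constructed so that FPKM + equal-split aggregation
  recovers the AFT matrix *exactly* (to per-sample closure). Lengths are
  Uniform(300, 3000) bp.
* **Taxa** — `X_PG = (W B^T) * noise` with a block-structured taxa x profile
  incidence `B` (8 signature taxa per profile plus weak background).

What the generator does **not** emulate: compositional coupling between
features induced by sequencing depth, phylogenetic correlation between taxa,
overdispersed zero inflation, batch/cohort effects, or any real annotation
noise (multi-annotations are planted, not inferred). Passing tests therefore
demonstrate correctness of the estimation machinery under the stated noise
model, not performance on real cohort data.

## Problem sizes and budgets

The study-condition checks run at n = 300 samples x 101 AFTs with planted
k = 4 (profile recovery at noise CV 0.1; selection recovery over
k in {2..6} at CV 0.2 across 5 seeded replicates, 2x2 bi-CV folds, 4
subsamples, reduced fit budget). Unit tests use a 6-AFT toy chain network
where the full network adds nothing. The solver-correctness suite compares
both half-updates against scipy-based QP oracles on 200 random instances up
to 6 samples x 8 features x 3 profiles.

## Known limitations

* The packaged metabolite topology and the 155-row constraint matrix are a
  synthetic reconstruction of the published network figure (exact published
  topology and F rows are not machine-readable); the KO memberships and
  GH/PL family list are the published selection. Loading a user-supplied F
  TSV overrides the stand-in.
* The BCD objective is jointly nonconvex; restarts mitigate but do not
  eliminate local minima. Profiles are identifiable only up to permutation
  and scale, hence the canonical ordering and frequency convention.
* Bi-CV requires held-out blocks with substantially more features than
  profiles; with p ~ k the scheme degenerates (guarded by errors).
* DI depends on the reference set; with few reference individuals the
  same-individual exclusion can leave samples undefined (NaN, warned).
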