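# Methods

## The statistical model

`gradcoda` fits a multivariate generalized linear mixed model for
point-count compositions on a gradient.  Counts **y**ᵢ (s categories,
total nᵢ) at standardised gradient position zᵢ are modelled as

    y_i ~ multinomial(n_i, ρ_i),      ρ_i = ilr⁻¹(x_i),
    x_i = β₀ + β₁ z_i + ... + β_d z_i^d + ε_i,     ε_i ~ N(0, Σ),

with d ∈ {1, 2, 3} (default 2) and x in isometric-logratio coordinates of
an orthonormal logcontrast basis V (s × (s−1), VᵀV = I, zero column sums).
The multinomial arises from points drawn independently within an
observation; ε absorbs extra-multinomial variation (spatial clustering of
colonial organisms, varying field of view), giving a logistic-normal
distribution of expected compositions.  Zeros are data, not a problem:
only the linear predictor is back-transformed (ilr⁻¹ = softmax ∘ V), so
observed zero counts need no pseudocounts and the likelihood is exact.

The covariate is standardised to sample mean 0 and sample SD 1 (ddof = 1);
the centre and scale are stored with the fit, and all user-facing grids
are specified in original units (metres) and converted internally.

### Priors

All priors act on the ilr scale and are configurable via `PriorSpec`:

- β_jk ~ Normal(0, `beta_scale` = 5): weakly informative; on the clr scale
  a 1-unit move is an e-fold change of a part relative to the geometric
  mean, so SD 5 is diffuse.
- Σ = L Lᵀ, with L lower-triangular; diag(L) has half-Normal(0,
  `re_scale` = 2) priors (sampled as log-diagonals with the Jacobian
  included) and off-diagonal entries Normal(0, `offdiag_scale` = 1).
  This Cholesky-factor prior is proper and weakly informative on the
  marginal SDs of the per-observation effects while allowing arbitrary
  correlation structure.  It was chosen over a separated scale/LKJ
  parameterisation because the model's gradients are written analytically
  and the Cholesky-normal form keeps them simple and exactly testable.

### Sampling

The posterior over (β, L, ε) is explored by the package's No-U-Turn
sampler (slice variant with doubling trajectories), with dual-averaging
step-size adaptation towards `target_accept` = 0.9 and a diagonal mass
matrix re-estimated in doubling warmup windows.  The per-observation
effects use a non-centred parameterisation (ε_i = L η_i, η_i ~ N(0, I)) to
avoid funnel geometry in the ~10³-dimensional posterior (e.g. 125
observations × 8 coordinates at the default study shape).  All gradients
of the log posterior are analytic; the multinomial term needs only one
(N × s) softmax per evaluation, so a reduced fit (2 chains × 300 warmup +
300 draws) takes ~15 s and the default (4 × 1000 + 1000) a few minutes on
one CPU.

Convergence is gated on split-R̂ ≤ 1.01 over all β components and zero
divergences (energy error > 1000).  `fit(..., on_bad_fit="raise")` is the
default; the reduced-settings runs used in tests and simulation studies
pass `"warn"`, because with ~300 retained draws per chain the R̂ noise
floor sits slightly above the gate even for well-mixing chains (observed
R̂ ≈ 1.01–1.02 with zero divergences and ESS in the hundreds).

### Model comparison

Expected log predictive density is estimated by PSIS leave-one-out over
observations (arviz).  Because each observation owns a random effect, the
pointwise likelihood is the *integrated* one: for each posterior draw,
p(y_i | β, Σ) is estimated by Monte Carlo over 100 fresh ε ~ N(0, Σ_draw)
(shared across observations within a draw; the estimate is insensitive to
raising the inner sample size to 400).  Pairwise elpd differences use the
paired pointwise SE.  Pareto-k diagnostics above 0.7 are counted and
reported per model.

A note on nested comparisons: with the diffuse default priors, a model
with extra coefficients whose true values are zero pays a LOO penalty
close to the number of extra effective parameters (≈ 8 when adding a cubic
term at s = 9) against a paired SE of 2–4, so the higher-degree model can
rank a few SEs below the true degree while being practically equivalent
(a deficit of ~7 on an elpd scale of thousands).  This is expected
behaviour of cross-validation on nested models, not evidence for the
smaller model being "significantly" better in any practical sense.

## Simplex geometry and calculus

`simplex` implements Aitchison geometry from first principles:
compositions are stored closed (unit sum, strictly positive, tolerance
1e-12 on the sum); perturbation/powering/difference work on the log scale
to avoid overflow; clr⁻¹ re-centres inputs whose sum drifts from zero by
less than 1e-8 and rejects worse.  Zeros are rejected at the composition
level by design — they are handled only at the count level by the
multinomial model.

The default ilr basis is built from the sequential binary partition that
splits {1..j} against {j+1} for j = s−1 … 1, with the standard balance
coefficients (+√(t/(r(r+t))) / −√(r/(t(r+t))) for r parts against t
parts).  Any valid SBP sign matrix is accepted (validated as a nested
hierarchy), and a helper draws uniformly random orthonormal logcontrast
bases for invariance testing.  Every distance-, norm- or
composition-valued output of the package is basis-invariant; the basis
affects only coordinate labelling, and the test suite asserts invariance
across random bases at 1e-8–1e-10.

`curves` represents the fitted gradient curve by its coefficient rows
β₀…β_d.  Evaluation, differentiation and integration are exact termwise
operations on the coefficients; the factorized two-point dissimilarity
|z₁−z₂|·‖β₁+(z₁+z₂)β₂‖ is used for degree ≤ 2 and verified against the
direct Aitchison distance at 1e-10 (degree 3 falls back to the direct
computation).  The collinearity check uses the least-squares multiplier
c = (β₁·β₂)/‖β₁‖² with relative residual tolerance 1e-6 by default; for
posterior draws, collinearity should be judged from posterior summaries
(e.g. the powering-line construction on a 3-part subcomposition), not a
point test.

## Synthetic data

The generator draws exactly from the model: uniform gradient positions on
a declared range, multivariate-normal observation effects, softmax of the
ilr predictor, multinomial counts.  The packaged "dock-like" truth mirrors
a fouling-community survey: 125 observations, 9 categories, 100 points
each, depths 0.11–3.72 m, quadratic trend.  Its clr-scale coefficients
were designed so that (i) one category ("algae") exceeds 0.7 of the
community at the shallow end and falls below 0.01 past mid-range, (ii)
"bare" rises monotonically to dominance at depth, (iii) two categories
peak at interior depths, (iv) one rare category stays below 0.02
everywhere while its clr trend rises, and (v) no true part ever falls
below 1e-4, so zero counts arise from sampling rather than degenerate
truth.  Overdispersion uses marginal SD 0.25 per ilr coordinate with
AR(1)-style correlation 0.4^|i−j| — moderate, and clearly detectable as a
Pearson dispersion ratio ≈ 1.4 at n = 100.

The truth curve is defined against a *fixed reference* standardisation
(range midpoint, uniform SD) so that the truth is identical across
replicate datasets; when a fit standardises by its own sample moments, the
truth is re-expressed in the fit's coordinates by exact polynomial
composition before any comparison.

What the generator does not emulate: spatial correlation of points within
an image beyond what ε induces, transect-level grouping (the model's
random effect is per observation, and a grouping column is only provided
for future use), identification error, and non-uniform depth sampling.
Passing recovery tests therefore shows correctness of inference under the
model's own assumptions, not robustness to their violation.

## Summaries

- HPD intervals: shortest contiguous interval containing ⌈level·n⌉ sorted
  draws (cross-checked against arviz).
- Dissimilarity surface: pairwise factorized distances per draw on a
  depth grid; reported as the posterior-mean matrix and the HPD-width
  (upper−lower) matrix, both symmetric with exactly zero diagonals.
- Rate profile: ‖D⊕M(z)‖ₐ per draw; the chain rule (×1/z-scale) converts
  to per-metre units by default, since depth grids are in metres; the
  per-standardised-z rate is available via `per_metre=False`.  Per-draw
  minimising depths use the closed form z* = −(β₁·β₂)/(2‖β₂‖²) for
  quadratics.
- Integrated composition: the simplex mean value over [S, D] per draw
  (invariant to the affine covariate standardisation), summarised per
  category.
- Bray–Curtis dissimilarity between adjacent grid compositions is included
  deliberately as a contrast: it is not perturbation invariant, and the
  tests exhibit curves where it ranks grid cells differently from the
  Aitchison rate.
- PCA of posterior-mean observation scores (polynomial prediction + ε):
  centred SVD with a deterministic sign convention (largest-magnitude
  loading positive).

## Numerical and design notes

- `power`, `ilr_inv` and all softmax-like reductions subtract the running
  maximum before exponentiating, so powering with |α| up to ~500 and
  extreme log-predictors stay finite.
- Degenerate inputs: constant covariate, rows with zero totals, empty SBP
  sides, the identity composition in `powering_line`, β₁ = 0 in the
  collinearity check and D ≤ S intervals all raise with specific messages.
- Sampler determinism: chains derive their generators from
  `SeedSequence(seed).spawn`, so any fixed seed reproduces counts, draws
  and replicates bit-for-bit on one platform.
- Problem sizes in the shipped studies were chosen to keep the full
  simulation-and-refit suite comfortable on a single CPU: recovery uses
  20 replicates at 2 × (300 + 300) draws, model comparison one dataset and
  three fits at the same settings, and the LOO inner integration 100
  samples; all are arguments, and the defaults for a one-off analysis
  are 4 × (1000 + 1000).

## Known limitations

- Σ is weakly identified at n ≈ 100 points per observation: its posterior
  mean overshoots small true variances (the likelihood bounds it from
  below much more sharply than from above).  β recovery is unaffected
  (coverage ≈ 0.88–0.90 in the shipped study).
- PSIS-LOO with Monte-Carlo-integrated random effects inherits both PSIS
  and inner-MC noise; Pareto-k counts are reported and refitting flagged
  observations exactly is left to the user.
- A single continuous covariate; multiple covariates would need only a
  design-matrix generalisation of the polynomial design but are not
  implemented.
- Plotting is intentionally out of scope; all summaries return tidy
  arrays/frames ready for any plotting stack.
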