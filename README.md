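# gradcoda

Compositional data analysis of community relative abundances along an
environmental gradient.

Ecological point-count data — which taxon sits under each of *n* random
points in an image — carry information only about *relative* abundances.
Such data are compositional: a community is an equivalence class of
positive vectors under scaling, canonically a point on the open simplex.
`gradcoda` is for ecologists (and anyone with counts-plus-a-covariate data)
who want a model-based, fully Bayesian analysis of how composition changes
along a gradient, with all downstream summaries done in the geometry where
compositions actually live.

## The model

For observation *i* with count vector **y**ᵢ (s categories, total *n*ᵢ) at
centred-and-scaled gradient position *z*ᵢ:

```
y_i  ~ multinomial(n_i, ρ_i)
ρ_i  = ilr⁻¹(x_i)
x_i  = β₀ + β₁ z_i + β₂ z_i² + ε_i ,   ε_i ~ N(0, Σ)
```

The linear predictor lives in isometric-logratio (ilr) coordinates, an
orthonormal logcontrast system in which the simplex operations of
perturbation (⊕) and powering (⊙) become ordinary vector addition and
scalar multiplication.  Zero counts sit naturally in the multinomial
support — the model never logratio-transforms the data, only the
predictor, so no pseudocounts are needed.  The per-observation effects
ε capture overdispersion (a logistic-normal distribution of expected
compositions).  Fitting is by the package's No-U-Turn sampler with
analytic gradients.

Because ilr is a linear isometry, the fitted curve
M(z) = γ₀ ⊕ (z⊙γ₁) ⊕ (z²⊙γ₂), with γⱼ = ilr⁻¹(βⱼ), supports calculus done
directly in the simplex:

- **Dissimilarity surface** — the Aitchison distance between expected
  compositions factorizes as ‖M(z₁) ⊖ M(z₂)‖ₐ = |z₁−z₂| · ‖γ₁ ⊕ ((z₁+z₂)⊙γ₂)‖ₐ,
  which also shows the same composition recurs at two gradient positions
  only when γ₂ is a powering of γ₁ (checked by `collinearity_check`).
- **Rate of change** — the simplex derivative D⊕M(z) = γ₁ ⊕ (2z⊙γ₂) is a
  composition; its Aitchison norm is a scalar rate that is zero exactly
  when nothing changes.
- **Gradient-integrated mean** — the simplex mean value
  (1/(D−S)) ⊙ [ (z⊙γ₀) ⊕ (z²/2⊙γ₁) ⊕ (z³/3⊙γ₂) ]ˢᴰ summarises the whole
  vertical slice in one composition.

Every summary is invariant to the choice of ilr basis.

## Worked example

`examples/03_fit_and_summarise.py` simulates a dock-wall-like survey
(125 stills × 9 categories × 100 points, depths 0.11–3.72 m), fits the
quadratic model and prints the posterior summaries:

```
simulated 125 stills x 9 categories, depths 0.13-3.71 m, 35% zero cells
sampler diagnostics: {'rhat_beta_max': 1.009..., 'divergences': 0, 'converged': True}

clr trends (mean [95% HPD]):
  0.2 m: most extreme category 'algae': +5.74 [+5.39, +6.22]
  3.6 m: most extreme category 'bare': +6.06 [+5.71, +6.43]

dissimilarity between 0.31 m and 3.56 m: mean 8.97, 95% HPD width 2.11
rate of change minimised near 2.08 m (2.70 per metre; ...)

depth-integrated mean composition (posterior mean [95% HPD]):
  bare               0.748 [0.727, 0.767]
  solitary_ascidian  0.075 [0.066, 0.084]
  ...
```

Reading this: the algal belt dominates the surface (clr +5.7 means algae
sit far above the geometric mean of all categories there), bare substrate
dominates at depth, the community turns over fastest at the ends of the
depth range with the quietest zone near 2 m, and in the simplex-mean
community over the whole wall the bare category carries ~0.75 of the
points.  The other examples cover the Aitchison algebra (`01`), simplex
calculus and the zero-dissimilarity condition (`02`), LOO degree selection
(`04`) and a parameter-recovery study (`05`).

A thin CLI wraps the same pipeline:

```bash
gradcoda simulate --seed 1 --out counts.csv
gradcoda fit counts.csv --chains 2 --warmup 400 --draws 400 --out fit
gradcoda rate fit --outdir summaries      # also: dissimilarity, integrate
gradcoda compare counts.csv               # LOO over degrees 1/2/3
```

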