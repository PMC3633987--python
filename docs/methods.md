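# Methods

## Model

`betaboost` fits a beta regression in which both distribution parameters
carry their own additive predictor.  A response y in (0, 1) is modelled
as Beta(a, b) with a = μφ and b = (1 − μ)φ, so that

    E[y]   = μ,
    Var[y] = μ(1 − μ) / (1 + φ),

a scaled version of the binomial variance; φ is a precision
(inverse-dispersion) parameter.  The links are

    logit(μ) = η_μ = β0 + Σ_j f_j(x_j),
    log(φ)   = η_φ = γ0 + Σ_j s_j(x_j),

where each f_j / s_j is a linear term, a dummy-coded factor block, a
P-spline, or a bivariate tensor-product surface over coordinates.  Under
the logit link, exp(β) is the multiplicative change in the odds
μ/(1 − μ) per unit change of a predictor, exactly as in logistic
regression.  Regressing φ on covariates ("variable dispersion") lets the
model absorb overdispersion that varies across the covariate space —
something neither logistic regression nor a fixed-dispersion beta model
can do.

## Estimation: cyclic componentwise boosting

The model is estimated by componentwise gradient boosting of the beta
log-likelihood, in the two-parameter (GAMLSS) flavour.  Each iteration
performs two half-steps:

1. **Mean half-step.**  Holding φ fixed, compute the score vector
   u = ∂ℓ/∂η_μ = φ·[logit(y) − ψ(μφ) + ψ((1 − μ)φ)]·μ(1 − μ)
   (ψ is the digamma function).  Fit every candidate base-learner to u
   by penalized least squares, select the one with the smallest
   (weighted) residual sum of squares, and add ν times its coefficient
   increment to that learner's accumulated coefficients.
2. **Precision half-step.**  Holding μ fixed, do the same with
   u = ∂ℓ/∂η_φ = φ·[ψ(φ) − μψ(μφ) − (1 − μ)ψ((1 − μ)φ)
   + μ·log y + (1 − μ)·log(1 − y)].

Both score expressions are derived analytically through the links and
certified in the test suite against central finite differences of the
log-likelihood (1e-6 relative tolerance on randomized grids); the
expected score is also checked to vanish at the generating parameters by
Monte Carlo.

The minimal-SSE selection rule is the standard inner L2 approximation of
"best improvement of the log-likelihood": to first order the likelihood
gain of a shrunken update is proportional to how well the learner
reproduces the score vector.  Ties (exactly equal SSE) go to the learner
declared first, making fits bit-reproducible.

Because every update is a *shrunken* fit of the current gradient, the
training negative log-likelihood is non-increasing across half-steps;
this is asserted on every fixture.  With unpenalized learners and m → ∞
the coefficients converge to the variable-dispersion maximum-likelihood
estimate (verified against direct numerical optimization); stopping
early is what regularizes and selects variables.

### Initialization

The offsets default to moment-matched maximum-likelihood intercepts:
η_μ(0) = logit(ȳ) and η_φ(0) = log(ȳ(1 − ȳ)/s² − 1).  `init="zero"`
starts both predictors at zero (μ = 0.5, φ = 1) instead — the schematic
textbook initialization.  The two differ only in how many iterations are
spent on the intercepts; both are exposed because the choice interacts
with very small m.

### Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `m_stop` | 1000 | iteration budget; the effective value is CV-chosen |
| `step_length` (ν) | 0.1 | shrinkage per update; the framework convention |
| `init` | `ml` | offset initialization (`ml` or `zero`) |
| `fixed_precision` | off | restrict the φ submodel to its intercept |
| spline knots / degree / penalty order | 20 / cubic / 2nd differences | P-spline shape |
| df per learner | smooth 1, categorical 1, linear part 2, tensor 6 | see below |

## Base-learners and fair selection

Every base-learner is a penalized least-squares smoother
B(B'WB + λK)⁻¹B'W with λ calibrated so that the trace of its hat matrix
equals a prescribed df (Demmler–Reinsch eigenvalues for the monotone
root search, polished against the exact trace; the calibration is exact
to 1e-6 even for ill-conditioned tensor designs).  Holding all
candidates at comparable df prevents componentwise selection from
favouring flexible learners merely for their extra parameters.

Continuous predictors enter decomposed into an **unpenalized linear
part** ([1, x], df 2) and a **centered smooth part**: the spline basis
is rotated into the difference-penalty's eigenspace, the penalized
directions are rescaled so the penalty becomes the identity, and the
resulting columns are residualized against {1, x} (df 1).  If only the
linear part is ever selected the effect is exactly linear; the smooth
part captures pure curvature.  The two parts are orthogonal by
construction, so their separate fits of any working residual sum
*exactly* to the joint penalized fit on the combined basis — the package
treats that combined basis (polynomial part unpenalized in the {1, x}
parameterization) as *the* P-spline.  This is a deliberate
parameterization choice: the raw difference penalty's null space is
index-linear in the coefficients, which under clamped boundary knots is
not exactly linear in x, and reconstruction against that
parameterization would hold only to ~1e-3 at the boundaries.  The two
function spaces are identical (B-splines reproduce x exactly through
the Greville abscissae; verified to 1e-15 in the tests).

Factors are dummy-coded with one column per level and a ridge penalty,
so sparsely observed levels are shrunken toward zero rather than
estimated freely; the shrunken level means follow n_g ȳ_g/(n_g + λ).
Spatial fields use a row-wise Kronecker product of two marginal cubic
B-spline bases (8 inner knots each) with penalty K₁⊗I + I⊗K₂ and a
single λ calibrated to df 6 — coordinates are treated as planar.
Spline evaluation outside the training range extrapolates the boundary
polynomial with a logged warning; effect curves should be read on the
interior of the support.

Continuous predictors in linear learners are standardized internally for
conditioning; reported slopes are rescaled to the original units.

## Early stopping

m_stop is chosen by bootstrap cross-validation: each fold draws n
observations with replacement (handled as integer case weights, which is
provably identical to physically replicating rows and keeps all design
matrices aligned), fits one boosting path, and records the mean negative
beta log-likelihood of the out-of-bag observations (the ~e⁻¹ ≈ 36.8% of
indices never drawn) along the path.  The m minimizing the across-fold
mean risk wins.  One path per fold is fitted and read out at grid
points, which is identical to — and ~|grid| times cheaper than — one fit
per candidate m.  A single shared m serves both submodels; a
two-dimensional (m_μ, m_φ) search buys little and is deliberately not
implemented.  The method default is 25 folds; the test suite and
acceptance script use 5–10 folds and coarser grids, which is sufficient
to locate the flat region of the risk curve at the problem sizes used.

## Evaluation toolkit

*Generalized R²* (likelihood-ratio form): R² = 1 − exp(2(ℓ₀ − ℓ₁)/n)
against the intercept-only model of the same family — 0 at no gain,
strictly below 1, invariant to adding constants to both log-likelihoods.
The *predictive* variant evaluates both the fitted model and the
training-data null model on held-out observations and may be negative.

*Baselines.*  Three Gaussian transformation models — identity, arcsine
square root, logit — are fitted by componentwise L2 boosting with the
same learners, step length and CV stopping as the beta model, plus a
fixed-precision beta model (φ-submodel restricted to its intercept).
To compare likelihood-based R² across families, Gaussian likelihoods
are mapped to the original (0, 1) scale by the change-of-variables
Jacobian |t'(y)| (1/(2√(y(1−y))) for arcsine, 1/(y(1−y)) for logit);
a flag switches to transformed-scale likelihoods instead.  Note the
arcsine transform maps into (0, π/2), so its implied original-scale
density integrates to the Gaussian mass over that image — slightly
below one; the Jacobian itself is verified by numerical integration.

The comparison harness draws bootstrap replicates, refits every flavor
per replicate via case weights, and scores out-of-bag predictive R².
One simplification relative to the full protocol: m_stop is chosen once
per flavor by bootstrap CV on the complete sample, not separately inside
every bootstrap replicate.  The choice is identical in expectation and
~20× cheaper; at the default problem size the ordering of flavors is
unaffected.

*QQ diagnostic.*  Plotting positions (i − 0.5)/n against a
moment-matched normal or an ML-fitted beta reference (bivariate
Nelder–Mead from moment starts), summarized by the maximum absolute
deviation.

*Boundary values.*  The beta density is undefined at 0 and 1; raw data
touching the boundary are mapped through (y(n − 1) + 0.5)/n.  The whole
vector is transformed whenever any value sits on the boundary (per-value
adjustment would distort ranks), and the sample records that it
happened.

## Synthetic data

The generator emulates a national lake-survey design: n = 994 sites,
78 predictor columns (77 continuous, one 12-level region factor with
sparse cells), planar coordinates on the unit square, and a beta
response whose mean and precision both depend on predictors.  Active
effects are fixed library shapes chosen to resemble benthic-invertebrate
ecology: a sigmoidal decay in developed land, an inverted-U in
elevation, negative linear trends in depth and log-nitrogen, a positive
linear trend in conductivity, region offsets of ±0.05–0.23 on the logit
scale, a smooth two-bump spatial field (amplitude 0.5), and — in the
precision submodel — a U-shape in log-chlorophyll-a plus a negative
linear turbidity trend.  Effect amplitudes are ~0.3–1.0 on the linear
predictor scales, the range typical of strong but realistic ecological
gradients.  Skewed water-chemistry variables are drawn log-normally and
emitted both raw and log-transformed (the truth acts on the log scale),
mimicking standard preprocessing and adding realistic collinearity.
The remaining 68 continuous predictors are inert noise.

What the generator does *not* emulate: real covariate correlation
structure beyond the raw/log pairs, measurement error in predictors,
exact zeros (available only via the `contaminate_zeros` option),
non-uniform spatial sampling, or any actual survey's covariate
distributions.  Passing recovery tests therefore demonstrates that the
estimator recovers the kinds of structure it models, not that any
particular field dataset satisfies those assumptions.

All randomness flows from one top-level seed; identical config + seed
reproduces every output byte-for-byte.

## Numerical choices

- μ is clipped to [1e-10, 1 − 1e-10] and φ to [1e-10, 1e10] inside link
  inversions; boosting can transiently produce extreme predictors.
- Singular unpenalized normal equations are ridge-stabilized (1e-8
  relative) with a logged warning.
- Non-finite losses or scores abort with the iteration, submodel and
  learner named.
- Out-of-bag risk cells that come out non-finite (extreme extrapolation)
  are set to +∞ with a warning rather than poisoning the mean.
- Bootstrap folds with an empty out-of-bag set are redrawn (relevant
  only at tiny n).

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` run the full pipeline at
n = 300–994 with 10–20 simulation or bootstrap replicates, 5–10 CV
folds and iteration grids up to 400–600 — sizes at which every
qualitative property (selection behaviour, recovery error, flavor
ordering) is stable across seeds while a complete run stays in the
minutes range.

## Known limitations

- Only logit/log links; no probit/cloglog, no beta-binomial or
  zero/one-inflated variants.  Exact boundary values must go through
  the boundary adjustment.
- One shared stopping iteration for both submodels; when the two
  submodels need very different complexity the φ submodel is typically
  somewhat over-shrunk (visible as conservative dispersion-effect
  amplitudes).
- Selection is mildly liberal, as is characteristic of boosting:
  inert predictors are picked in a minority of fits near the CV-chosen
  m; specificity is reported by the recovery harness rather than
  guaranteed.
- The spatial learner assumes planar coordinates; no great-circle
  correction.  Tensor-product boundary artefacts can appear where data
  are sparse.
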