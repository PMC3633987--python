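# betaboost

Boosted beta regression for proportion outcomes: componentwise gradient
boosting of a beta-distributed location–scale model in which **both the
mean and the precision** get their own additive predictor.

Percentage and proportion responses — the share of a species assemblage,
land-cover fractions, rating scales mapped to (0, 1) — violate the
assumptions of ordinary least squares: their variance shrinks toward the
boundaries, they are frequently overdispersed relative to a binomial
benchmark, and the classic fixes (arcsine-square-root or logit
transformation followed by a Gaussian model) sacrifice interpretability
on the original scale.  Beta regression models the response directly as

    y ~ Beta(μφ, (1 − μ)φ),    E[y] = μ,    Var[y] = μ(1 − μ)/(1 + φ),

with logit(μ) and log(φ) each an additive combination of linear terms,
dummy-coded factors, P-splines, and a tensor-product spatial surface.
Fitting is by cyclic componentwise gradient boosting of the beta
log-likelihood: per iteration, each submodel updates only its single
best-fitting base-learner by a small shrunken step, so variable
selection happens *during* estimation.  The stopping iteration — the
model's regularization parameter — is chosen by bootstrap
cross-validation of out-of-bag predictive risk.  Under the logit link,
exp(coefficient) is the multiplicative change in the odds μ/(1 − μ), as
in logistic regression.

The package targets applied statisticians and quantitative ecologists
who need sparse, interpretable mean *and* dispersion models for bounded
responses with many candidate predictors.  It ships a synthetic-data
generator emulating a national lake-survey design (≈1000 sites, 78
mixed-type predictors, sparse region factor, spatial field), so every
claim is testable without any external dataset.  See
[docs/methods.md](docs/methods.md) for the full model account.

## Worked example

```sh
betaboost simulate --preset nla-like --seed 1 --out sim
betaboost cv sim/data.csv --m-stop 400 --folds 25 --seed 1 --out run
betaboost fit sim/data.csv --m-stop 200 --seed 1 --out run
betaboost predict sim/data.csv --model run/model.json --out run
betaboost evaluate sim/data.csv --replicates 20 --cv-folds 5 --m-stop 400 --seed 1 --out run
```

The same workflow from Python, on a fresh synthetic dataset:

```python
import betaboost as bb

spec = bb.nla_like_spec(seed=1)          # 994 sites, 78 predictors
df, truth = bb.generate(spec)

cfg = bb.AnalysisConfig(response="y", coordinates=("lon", "lat"))
cfg.continuous = [c for c in df.columns if c not in ("y", "lon", "lat", "region")]
cfg.categorical = ["region"]
factory = bb.make_learners(df, cfg)

sample = bb.ProportionSample(df["y"].to_numpy(), len(df))
lmu, lphi = factory()
model = bb.boost_fit(sample, lmu, lphi, bb.BoostConfig(m_stop=300))

report = bb.recovery_report(truth, model, df)
print(round(report["sensitivity_mu"], 2), round(report["sensitivity_phi"], 2))
for (sub, col), m in report["per_effect"].items():
    print(f"{sub:3s} {col:13s} rel. curve RMSE = {m['rel_rmse']:.3f}")
```

Output:

```
1.0 1.0
mu  dev_land      rel. curve RMSE = 0.052
mu  elevation     rel. curve RMSE = 0.092
mu  depth         rel. curve RMSE = 0.046
mu  log_nitrogen  rel. curve RMSE = 0.051
mu  conductivity  rel. curve RMSE = 0.024
phi log_chla      rel. curve RMSE = 0.069
phi turbidity     rel. curve RMSE = 0.040
```

Every true effect — in the mean *and* in the precision submodel — was
selected (sensitivity 1.0), and each estimated partial-effect curve
deviates from the generating truth by under 10% of that effect's
amplitude.  A coefficient of, say, 0.20 on a region dummy means the
odds of the proportion rise by the factor `bb.odds_factor(0.20) ≈ 1.22`
for lakes in that region.

The `evaluate` subcommand prints the median out-of-bag predictive
generalized R² per model flavor; on beta-generated data the boosted
beta model leads, followed by the fixed-precision beta model, with the
three Gaussian transformation baselines behind.

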