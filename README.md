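# heckcrash

Heckman sample-selection modelling of crash rate and injury severity at
signalized intersections.

## The problem

Road-safety studies want to explain the *crash rate* of an intersection —
crashes per million vehicles of annual exposure (AADT × 365) — separately
for each injury-severity level: slight injury versus KSI (killed or
seriously injured). But a severity-specific crash rate is only observed at
an intersection-year when crashes of that severity actually occurred.
Fitting least squares to the observed rates alone ignores this selection
and biases the estimates whenever the unobservables that make a severity
level *occur* are correlated with the unobservables that drive the *rate*.

The Heckman selection model treats this head on with two equations:

- outcome: `y_i = x_i'β + μ_i`, the severity-specific crash rate,
- selection: the rate is observed iff `z_i'γ + υ_i > 0`,

with `μ ~ N(0, σ²)`, `υ ~ N(0, 1)` and `corr(μ, υ) = ρ`. A nonzero ρ is
exactly the selection bias / endogeneity between crash occurrence and
crash rate.

Two estimators are provided:

- **Two-step (LIML)** — probit of the selection flag on `Z`, then least
  squares of `y` on `[X, λ(z'γ̂)]` over the selected rows, where
  `λ(a) = φ(a)/Φ(a)` is the inverse Mills ratio. The Mills coefficient
  estimates the selection coefficient `ρσ`; `σ̂` and `ρ̂` are backed out
  and standard errors corrected for both the generated regressor and the
  induced heteroskedasticity.
- **FIML** — joint maximization of the full likelihood
  `Σ_{s=0} log(1−Φ(z'γ)) + Σ_{s=1} [log Φ((z'γ + ρ(y−x'β)/σ)/√(1−ρ²)) +
  log φ((y−x'β)/σ) − log σ]`, with a Wald test of equation independence
  (ρ = 0).

Around them sit a synthetic-data generator with known truth (so every
estimator is verified by parameter recovery), a bivariate-probit
comparison model for the two severity indicators jointly, the
truncation-effect computation `ρ̂ × (average Mills value)` with its
percent interpretation `100(exp(·)−1)`, MAD/RMSE goodness of fit, and a
pipeline/CLI that renders publication-style coefficient tables.

## Worked example

Generate a synthetic network of 5,000 intersection-years with true
ρ = 0.6, σ = 0.5, then fit both estimators:

```
heckcrash simulate --n 5000 --rho 0.6 --sigma 0.5 --seed 7 --out demo.csv
heckcrash fit --data demo.csv --severity slight --method both \
    --outcome-col crash_rate --selection-col selected \
    --outcome-vars reciprad,cycletime,tramstop,kln \
    --select-vars aadt,reciprad,tramstop,kln,speed
```

prints (abridged):

```
Goodness-of-fit assessment
Rho     0.588
Sigma   0.486
Lambda  0.286
Number of observations  5000
Wald Chi-square 59.76
MAD     0.359
RMSE    0.450
Truncation effect       0.224
Percent shift   25.15
```

Read: the two-step estimate of the error correlation is ρ̂ = 0.588
(truth 0.6) with outcome error SD σ̂ = 0.486 (truth 0.5); the selection
coefficient λ̂ = ρ̂σ̂ = 0.286 holds by construction. The Wald statistic
59.8 (χ², 1 df) firmly rejects independence of the two equations, i.e.
ignoring selection would bias this regression. The truncation effect
ρ̂ × (average Mills value) = 0.224 means the conditional crash rate of
the selected sample sits about 25% above the population value at average
characteristics.

The same analysis is available programmatically:

```python
from heckcrash import hk_like_config, simulate_dataset, fit_two_step

ds = simulate_dataset(hk_like_config(n=5000, rho=0.6, sigma=0.5, seed=7))
fit = fit_two_step(ds.design())
print(fit.rho_hat, fit.sigma_hat, fit.lambda_hat)
```

For real data, `heckcrash fit --data records.csv --severity slight`
derives the severity outcome and selection flag from `slight_count` /
`ksi_count` and `aadt` columns; `heckcrash compare` fits the bivariate
probit; `heckcrash summarize` prints the sample-characteristics table.

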