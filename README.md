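# cdwheat

Threshold-regression analysis of cadmium transfer from soil to wheat grain.

## The problem

Cadmium in agricultural topsoil moves into wheat grain, and how strongly it
moves depends on soil conditions — pH, organic matter, texture, competing
elements (Zn, Ca, P), and the chemical form the Cd is in.  The usual tool,
a single multiple linear regression of grain Cd (or its soil-normalised
transfer ratio) on soil properties, forces every factor to act the same way
across the whole range of conditions.  Field data from contaminated
calcareous alluvium suggest otherwise: the same factor can promote transfer
on one side of a critical soil-pH or soil-Cd level and inhibit it on the
other.

`cdwheat` models this with a two-regime threshold regression.  The response
is the base-10 log of the bioconcentration factor,
BCF = [Cd]_grain / [Cd]_soil (both mg/kg dry weight), and for a predictor
x (pH, log[OM], soil P, ...) and threshold variable q (soil pH or total
soil Cd):

    log10(BCF_i) = a1 + b1 x_i + e_i   if q_i <= gamma   (regime 1)
    log10(BCF_i) = a2 + b2 x_i + e_i   if q_i >  gamma   (regime 2)

The threshold gamma is estimated by concentrated least squares over the
trimmed grid of observed q values; inference uses the likelihood-ratio
sequence LR(gamma) = n (S(gamma) − S(gamma_hat)) / S(gamma_hat), an
LR-inversion confidence set with critical value
c(alpha) = −2 ln(1 − sqrt(1 − alpha)), and a residual-bootstrap sup-F test
for whether a threshold exists at all (gamma is unidentified under the
single-line null, so the test is bootstrapped rather than tabulated).

Around the core estimator the package carries the full descriptive layer of
a soil-survey study — summary statistics with CV, Pearson correlation
tables with two-tailed significance flags, Tessier speciation percentages
(exchangeable / carbonate / Fe-Mn oxide / organic / residual Cd), and
regulatory exceedance screening against 1 mg/kg (agricultural soil) and
0.1 mg/kg (wheat grain) — plus a seeded synthetic-data generator that
emulates the marginal structure of a 22-sample survey, since such raw
survey data are typically not released.

## Worked example

```python
from cdwheat import (SyntheticConfig, ThresholdSpec, generate,
                     fit_threshold, bootstrap_test, predict)

data = generate(SyntheticConfig(n=22, seed=1))      # synthetic survey
spec = ThresholdSpec("log_bcf", "ph", "ph")         # pH as x and q
fit = fit_threshold(data, spec)
boot = bootstrap_test(data, spec, n_boot=499, seed=1)
print(fit.gamma_hat, fit.beta_low, fit.beta_high, boot["boot_p"])
```

prints

```
8.196256686670582 (-3.4626271808556512, 0.3120753061558854) (10.324107584045882, -1.3427271517264348) 0.032
```

i.e. on this draw the estimated pH threshold is 8.20 (the generator plants
7.98 with slopes +0.292 / −0.615; at n = 22 the estimate carries sampling
noise), log[BCF] *rises* with pH by 0.31 per unit below the threshold and
*falls* above it, and the bootstrap existence test rejects the single-line
null at the 5% level — the signature two-regime behaviour.  Predictions
follow the regime of the query point: `predict(fit, 7.5, 7.5)` evaluates
the lower-regime equation.

The same analysis end-to-end, as numbered drivers:

```sh
python analysis/01_simulate.py        # synthetic survey + null data
python analysis/02_descriptives.py    # summary stats, correlations, speciation
python analysis/03_threshold_fits.py  # 9 predictors x 2 threshold variables
python analysis/04_calibration.py     # oracle, recovery, coverage, test size
```

or through the CLI: `cdwheat simulate | describe | fit | run`.

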