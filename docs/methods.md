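# Methods

## Model

The quantity of interest is the bioconcentration factor of cadmium in the
soil–wheat system, BCF = [Cd]_grain / [Cd]_soil (mg/kg dry weight over
mg/kg dry weight), analysed on the log10 scale.  All logarithms in the
package are base 10, matching the convention in which soil–plant transfer
models are normally published; a natural-log fit would rescale every
coefficient.

For a predictor x and a threshold variable q the two-regime model is

    y_i = a1 + b1 x_i + e_i  if q_i <= gamma,
    y_i = a2 + b2 x_i + e_i  if q_i >  gamma,

with y = log10(BCF).  Ties at the threshold belong to the lower regime
(q <= gamma).  Each regime is a simple regression with its own intercept;
multi-predictor regimes are deliberately out of scope — the survey-scale
sample sizes (n ≈ 22) cannot support them per regime.

## Estimation

gamma is estimated by concentrated least squares.  Candidates are the
distinct observed values of q such that both regimes retain at least
max(ceil(trim_fraction · n), min_regime_size) observations; trimming
defaults to 15% per tail and min_regime_size to 3 (two coefficients plus
one residual degree of freedom).  S(gamma) is the sum of the two regimes'
residual sums of squares; gamma_hat is the grid argmin, ties broken toward
the smallest candidate (deterministic).

Because S(gamma) for adjacent candidates differs by moving a few points
between regimes, the whole grid is evaluated in O(n) from cumulative sums
of (x, y, x², y², xy) in threshold-sorted order, after centering x and y
to suppress cancellation.  A plain two-regression route (`ssr_at`, via
numpy lstsq) is kept alongside, and the calibration suite checks the two
routes agree exactly on random small datasets.  A regime in which the
predictor has (numerically) zero spread makes that candidate inadmissible
(+inf SSR); if every candidate is inadmissible the fit errors out.

## Inference

* **LR sequence.**  LR(gamma) = n (S(gamma) − S(gamma_hat)) / S(gamma_hat),
  equivalently (S(gamma) − S(gamma_hat)) / sigma2_hat with
  sigma2_hat = S(gamma_hat)/n (denominator n, not n − k, so confidence-set
  widths are reproducible from the reported SSR alone).  LR(gamma_hat) = 0
  by construction.  The sequence is homoskedastic by default, matching how
  such LR plots are usually reported.
* **Confidence set for gamma.**  {gamma : LR(gamma) <= c(alpha)} with
  c(alpha) = −2 ln(1 − sqrt(1 − alpha)) (7.3523 at alpha = 0.05).  S(gamma)
  is piecewise constant on [gamma_k, next distinct q), so the reported
  upper bound is the right edge of the last retained candidate's constancy
  interval; with the naive max-member convention a continuous true
  threshold falls outside the set almost surely when identification is
  strong, and measured coverage collapses.  Non-contiguous sets are
  reported with `contiguous = False` rather than silently convexified.
* **Existence test.**  sup-F = n (SSR_null − S(gamma_hat)) / S(gamma_hat),
  where SSR_null is the single-line OLS fit.  gamma is unidentified under
  the null, so the null law is approximated by a residual bootstrap: the
  design (x, q) is held fixed, responses are redrawn as fitted-null values
  plus residuals resampled with replacement, and each resample is
  re-scanned for its own sup-F.  p = (1 + m)/(B + 1) (never exactly zero);
  B defaults to 499, and 199 is used in the size study.  A threshold effect
  is declared at boot_p <= 0.05.
* **Degenerate fits.**  With an (essentially) perfect fit sigma2_hat = 0;
  the point estimate and coefficients are still returned, but the LR
  sequence, confidence set and sup-F are undefined and requesting them
  raises a degenerate-variance error.  "Essentially" means
  sigma2_hat <= 1e-10 × the response's squared scale, so zero-noise
  synthetic data take this path despite float fuzz.

## Descriptive layer

Summary statistics use the sample SD (n − 1) and CV = SD/mean × 100.
Exceedance against regulatory limits (1 mg/kg Cd for agricultural soil,
0.1 mg/kg for wheat grain) is strict (>).  Pearson correlations carry
two-tailed p-values from the t distribution with n − 2 df, starred at
0.05/0.01; each pair uses its own complete cases.  Tessier speciation
percentages are taken over the five-fraction sum rather than total soil
Cd, so imperfect sequential-extraction recovery (tolerated at ±10% of
total Cd, reflecting a 95 ± 5% recovery) cannot distort the ordering; the
non-residual share (100 − residual%) proxies the mobile, plant-available
pool.

## Synthetic data generator

The generator emulates a 22-sample topsoil/wheat survey on carbonate-rich
Yellow River alluvium.  Marginals (truncated at the survey's observed
ranges): total soil Cd lognormal with arithmetic mean 2.99 and SD 2.67
mg/kg on [0.42, 11.21] (CV ≈ 89% makes the lognormal the simplest family
matching both moments and skew); Zn lognormal (488 ± 837 mg/kg, CV ≈ 171%);
pH normal 7.88 ± 0.38 on [6.82, 8.78]; OM, CaCO3, Ca, Fe, Mn, P truncated
normal at their survey moments.  Truncated draws use inverse-CDF sampling,
so truncation costs no rejection loop; the realised moments sit slightly
inside the untruncated targets, which the moment-convergence test accounts
for by using wide bounds.  Clay and silt are drawn and sand closes the
composition, so clay + silt + sand = 100 exactly.  Tessier fractions are a
Dirichlet draw (concentration 200) around mean shares (13, 30, 15, 4, 38)%
for (ex, ca, fm, or, re), scaled by total Cd times a truncated-normal
recovery (0.95 ± 0.04 on [0.90, 1.05]), so the recovery invariant holds by
construction and the mean ordering re > ca > fm > ex > or is stable.

The response plants log10(BCF) = a + b·x per regime with defaults gamma =
7.98 on pH and coefficients (−3.337, 0.292) / (4.186, −0.615) — the
published pH-threshold model for this system.  noise_sd defaults to 0.15:
with the within-regime pH spread this puts per-regime R² in the 0.3–0.5
band typical of the published fits, and keeps BCF draws inside the
field-typical 0.04–0.23 range.  Grain Cd is back-computed as
soil_cd · 10^log_bcf, so derived columns reproduce the planted response
exactly.  `null_linear` mode applies the lower-regime line everywhere and
is the null for size studies.  One integer seed drives everything through
fixed per-variable substreams (seeding `default_rng([seed, stream_index])`),
so adding a variable to the schema does not shift existing draws.

Covariates are drawn independently by default; real surveys have
correlated covariates (e.g. Cd with Zn and P under shared industrial
sources), and nothing here emulates spatial structure or a pollution
gradient.  Passing tests therefore demonstrate correctness of the
estimator and bookkeeping under the stated marginal/regime structure, not
that any particular field dataset follows a threshold model.

## Calibration studies (problem sizes)

* Oracle agreement: 50 random two-regime datasets, n drawn in [12, 30];
  the fast scan must match the exhaustive per-candidate refit exactly.
* Recovery/coverage: 200 replicates, n = 200, q ~ U(0, 10), x = q, equal
  intercepts with slopes +1/−1 (slope gap 2), noise SD 0.2.  Reported:
  median |gamma_hat − gamma| against the local grid spacing at the true
  threshold, and 95% LR confidence-set coverage.  The uniform threshold
  variable makes grid spacing homogeneous so these are clean measurements.
* Size: 300 replicates, n = 200, single line y = 1 + 0.5q + noise
  (SD 0.3), 199 bootstrap draws, nominal level 5%.

## Known limitations

Single threshold and two regimes only — no multi-threshold search, panel
structure, kink/continuity constraints, or heteroskedasticity-robust LR
(an option point exists but the plain sequence is the default and the only
tested path).  The LR-inversion set is asymptotic; at n = 22 it is wide
and its coverage is only verified at n = 200.  Units are fixed (soil Cd,
Zn in mg/kg; Ca/Fe/Mn/P in g/kg; OM in %); there is no unit conversion on
input.
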