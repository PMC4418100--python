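# movespec

Spectral and hierarchical-Bayesian analysis of daily animal movement:
at what time scale do individuals in a population move *in synchrony*, and
how strongly is each individual's movement autocorrelated?

The package targets radiotelemetry-style data — one displacement distance
per individual per day over a contiguous window — and was built around a
study of six free-ranging northern death adders (*Acanthophis praelongus*)
tracked daily for 64 days. Synchronous displacement across individuals
points to shared external drivers (weather, seasonal prey availability);
its absence at a given time scale means movement there is governed by
individual-level factors. The method separates the two by frequency.

## The model

Daily displacements `D[t,n]` (individual `n`, day `t`) are right-skewed, so
they are power-transformed, `X = D**c`, with `c` chosen to minimise
`sum_n |skewness(D[:,n]**c)|`. Each transformed series of even length `L` is
decomposed by FFT into phases `theta[f,n]` and periodogram ordinates
`psi[f,n]` at whole-cycle frequencies `f = 1..l`, `l = L/2 - 1` (frequency
`f` corresponds to a time scale of `L/f` days).

**Synchrony.** Phases at frequency `f` are modelled either as wrapped
Cauchy, `P(theta | mu_f, rho_f) = (1/2pi)(1 - rho_f^2)/(1 + rho_f^2 -
2 rho_f cos(theta - mu_f))`, with common mean direction `mu_f` and
concentration `rho_f` (synchrony: `rho_f = 0` none, `rho_f -> 1` perfect),
or as circular-uniform. A cutoff `phi` splits the spectrum — synchronous
for `f <= phi`, uniform above — and the `rho_f` borrow strength through a
hierarchical beta distribution parameterised by mode `M` and shape
`nu = alpha + beta`, with a Uniform(0,1) prior on `M` and a gamma prior on
`nu` solved so that 95% of its mass lies in [5, 200]. Each candidate `phi`
(0..`l`) is fitted by adaptive Metropolis-within-Gibbs MCMC and compared by
the Deviance Information Criterion, `DIC = 2 p_D + D(xi_bar)`; differences
above 3 mark clearly less-supported models.

**Colour.** Ordinates follow the Whittle approximation,
`psi[f,n] ~ Exp(mean = a_n f**(-gamma_n))` — 1/f noise with individual
colour `gamma_n` (red > 0, white = 0, blue < 0) and nuisance scale `a_n`.
Individuals share population-level normals `gamma_n ~ N(gammabar,
sigma_gamma)` and `log a_n ~ N(abar_log, sigma_alog)`, with a conjugate
Normal(0, 4) / scaled-inverse-chi-squared(mode 0.0625, 95th pct 1) pair on
the colour hyperparameters and flat hyperpriors on the scale block. The fit
is checked by posterior-predictive periodogram bands and by standardised
residuals `Z = psi/Y` (serial correlation at lags 1/5/10; KS against the
unit exponential; a check flags misfit when >50% of posterior realizations
give p < 0.05).

A synthetic-data generator inverts the whole model (exponential ordinates,
wrapped-Cauchy/uniform phases, Hermitian inverse FFT), sharing the spectral
convention with the analyser exactly, so every stage is testable by
parameter recovery.

## Worked example

The numbered drivers under `analysis/` run the full chain on a synthetic
study generated at the original conditions (N = 6 individuals, L = 64 days,
synchrony at `f <= 3`, population colour mean 0.75):

```
$ python analysis/01_simulate_study.py --seed 1
wrote results/synthetic_study/panel.csv: N=6, L=64, true cutoff=3 (time scale 21 d), true population colour mean=0.75

$ python analysis/02_transform_and_spectra.py
transform exponent c = 0.2086 (objective 1.8913)
spectra: l = m = 31 frequencies for 6 individuals over L = 64 days

$ python analysis/03_synchrony_scan.py --seed 1
selected cutoff phi = 3 -> synchrony at time scales >= 21 days

$ python analysis/04_colour.py --seed 1
population colour mean = 0.90 [0.56, 1.23] (red noise)
  individual 1: gamma = 0.71 [0.35, 1.05]
  ...
```

The scan recovers the generating cutoff (`phi = 3`: synchrony only at time
scales of three weeks and longer), and the population colour interval
covers the generating value 0.75 — every individual's colour is clearly
positive, i.e. a long-moving day tends to follow a long-moving day.
`analysis/05_residuals_and_sensitivity.py` adds the residual checks and
re-runs the scan under all nine alternative hyperprior combinations.

The same stages are available as a CLI (`movespec transform | decompose |
synchrony-scan | colour | simulate | priors solve | report`); `movespec
report` chains everything, writing JSON/CSV results and figures whose
content is reproducible byte-for-byte from the seed.

To analyse real telemetry instead, point `analysis/02...` (or `movespec
report`) at a CSV in either dialect: daily fixes
`individual,date,easting,northing` (planar metric coordinates) or daily
distances `individual,date,distance`. Series must be gap-free; individuals
must share the date range.

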