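# Methods

## The model family

National production is treated as a partially observed Markov process on
a decadal grid. Per country *c*, the latent state *x* is log expected
production:

    x[c,t] = mu + rho·x[c,t−1]·[autoregression]
             + beta_gdp·z_gdp[c,t] + beta_cum·z_cum[c,t]
             + beta_diff·z_diff[c,t] + beta_cumdiff·z_cumdiff[c,t]
             + beta_int·z_gdp·z_diff[c,t]
             + sigma_proc·eps[c,t]
    log(Y[c,t] + offset) ~ N(x[c,t], tau_obs²)

Working on the log scale is what makes Gaussian machinery defensible:
the raw production values are fat-tailed (their individual-level
building blocks follow a power law with exponent near 1), and the log
transform absorbs that. An optional Student-t innovation switch
(`innovations="t"`) is available for residual heavy-tailedness; it is
only usable with the particle-filter likelihood.

Each hypothesis about the process (pure noise; own recent production;
economic development; own cumulative past; neighbours' recent output;
neighbours' cumulative output; a development×diffusion interaction)
toggles one term. The named ladder A…K covers the combinations of
interest; any flag set respecting the dependencies (the interaction
requires development and a diffusion term) is constructible.

**Plug-in covariates.** The diffusion covariates are computed from
*observed* neighbour production, not latent states, and lagged by one
grid step (a country cannot react to strictly contemporaneous output
elsewhere; the lag is configurable). This is a deliberate
simplification: it makes the panel likelihood factorize by country, at
the price of ignoring feedback through the latent states. Modelling
latent cross-country coupling is out of scope. All covariates enter
z-scored over the whole panel, so coefficients are comparable "scaled"
effects.

## Likelihood evaluation

Two backends share the model definition:

* **Bootstrap particle filter.** Particles are propagated through the
  process model, weighted by the measurement density, and resampled
  systematically at every step; the per-step log mean weights sum to the
  log-likelihood estimate. Particles are sorted by value before
  resampling, which makes the likelihood surface near-continuous in the
  parameters under common random numbers (CRN) — without it a
  derivative-free optimizer stalls on resampling discontinuities. The
  Monte Carlo standard error is assembled from per-step relative weight
  variances (delta method, treating steps as independent; an
  approximation that is accurate when weight degeneracy is mild). A step
  where all weights underflow raises a filtering error naming the
  country and step.

* **Exact Kalman recursion.** Given plug-in covariates and Gaussian
  innovations the per-country model is a univariate linear-Gaussian
  state space, so the exact likelihood is available. The recursion is
  vectorized across countries (the state variance is shared because the
  initial state is pinned).

The particle filter is validated against the Kalman value on
linear-Gaussian instances (agreement within 3 Monte Carlo standard
errors at 10⁴ particles); the test-suite oracle is an independent scalar
reimplementation of the filter, not the package's vectorized code.

**Initial state.** x0 is pinned to each country's first observed log
production (not estimated). Consequently the first grid year of each
country is conditioned on rather than scored, and `n_obs` for BIC is the
number of scored (country, year) pairs, i.e. countries × (steps − 1).

**Maximum likelihood.** Nelder-Mead on a transformed parameter space
(tanh for rho, log for the two scales) from one or more starts. The
particle objective is made deterministic by reusing the filter seed at
every evaluation (CRN), so fits are exactly reproducible. For the
particle backend two safeguards are added: a pilot exact-likelihood fit
is included among the starts when innovations are Gaussian (a cheap
consistent initializer), and each Nelder-Mead run is restarted once from
its own optimum to guard against premature simplex collapse on the
slightly jagged surface. Standard errors come from the numerical Hessian
of the exact likelihood at the optimum.

**Model comparison.** AIC = 2k − 2ℓ, BIC = k·ln(n_obs) − 2ℓ, with k the
number of free parameters of the flag set. Nested pairs are compared by
likelihood-ratio test with a χ² reference (df = difference in k);
negative deviances — possible only through optimisation noise — are
clipped to zero with a warning. In replicate studies the full model is
warm-started from the nested optimum, which keeps the LRT well
calibrated (type-I error at nominal 0.05 measured at ≈ 0.04 over 200
null replicates in the test suite).

## Productivity index and tail

The nine indicators are standardized (zero mean, unit sd) and projected
on the first eigenvector of their correlation matrix; correlation rather
than covariance because bytes and counts are incommensurate. The sign is
fixed so the score rises with the mean indicator. Missing cells are
imputed as the column minimum (absence from a language edition is the
notability floor), with a logged count; constant columns are dropped
with a logged warning, and an all-constant matrix is an error — there is
no meaningful ordering of identical individuals.

PC1 coordinates can be negative, but downstream aggregation needs
positive summable magnitudes. The `positivize` option maps the z-scored
coordinate *s* to `exp(scale·s)`: positive, heavy-tailed, order
preserving. How the original indicator construction handled this is not
determinable from the available description, so both the switch and the
scale are explicit configuration; the tail exponent of the positivized
scores depends on `scale`, which is why tail recovery checks run on the
generator's latent scores.

Tail estimation uses the Hill estimator in the CCDF convention,
`alpha_hat = n / Σ log(x_i/xmin)` over the tail x ≥ xmin (equal to the
density exponent minus one).

## Aggregation choices

* Peak-productivity age 35; window y ± 25 years with **both endpoints
  inclusive** ("between … and" is ambiguous; inclusive is the documented
  , configurable choice).
* Unknown birth years are imputed as death_year − 60 when a death year
  exists, otherwise the row is dropped; both counts are logged.
* Population anchors are linearly interpolated to the 10-year grid and
  linearly extrapolated from the two nearest anchors outside the range.
* Loess is local-linear with tricube weights and zero robustness
  iterations; the bandwidth is given in years and converted to a span
  fraction. Local-linear fits reproduce linear trends exactly, which the
  tests exploit.
* The log view uses log(x + offset) with the offset defaulting to half
  the smallest positive per-capita value, so zero cells stay finite.
* The top-10% split threshold is the empirical 90th percentile of
  scores; pooling relabels countries and is exactly additive in national
  products.

## Association models

The 50-year-spaced panel (no window overlap between data points) is fit
by profile maximum likelihood: given the variance ratio
γ = σ_u²/σ_e² and the AR coefficient φ, the fixed effects are GLS and
σ_e² has a closed form, leaving a two-dimensional search. The
"autoregressive random effect" is reconstructed as a country random
intercept plus AR(1) within-country residual correlation φ^(Δ steps);
the exact original structure is not published, and pinning γ = φ = 0
(`fit(fix_gamma=0, fix_phi=0)`) reduces the model to pooled OLS exactly,
which serves as an oracle in the tests. Wald t-tests use
containment-style df = n − p − n_countries. P-values are reported raw
(no multiplicity correction), matching standard reporting for this kind
of table.

## Synthetic data: what it emulates and what it does not

The generator draws latent scores from a Pareto truncated to
[xmin, xmax] (default [1, 10⁶]) with CCDF exponent alpha = 1 — the
truncation keeps the alpha = 1 case a proper distribution while leaving
the Hill estimate essentially unbiased (the truncation correction at the
default bound is ~10⁻⁵). Indicators are a_k + b_k·log s + Gaussian noise
with b_k > 0: with zero noise each indicator is a strictly increasing
transform of the score. The indicator-noise model is a stand-in — how
real notability noise relates to latent importance is unknown — so
passing tests certify the pipeline's statistical machinery, not the
fidelity of any particular indicator-noise mechanism. Birth years are
uniform on the study window, countries multinomial with configurable
weights, capitals a deterministic Europe-sized scatter unless supplied.

Panels are forward-simulated from the canonical process. Exogenous
covariates are geometric random walks (GDP per capita with mild positive
drift, population), a logistic-transformed walk for urbanisation. When a
diffusion term is active during *generation*, the lagged raw diffusion
value enters scaled by a user-supplied constant (it cannot be z-scored
before the panel exists); fitting always uses the z-scored plug-in
columns. All replicate studies in the tests generate under nulls where
this distinction is moot.

Default process parameters (mu 0.4, rho 0.6, beta_gdp 0.3, sigma 0.3,
tau 0.4) define the standard simulation conditions used throughout the
tests; replicate studies use 10 countries × 30 decadal transitions
(parameter recovery uses 55) — sizes chosen as the smallest at which the
asymptotic χ² and AIC behaviour is stable.

## Known limitations

* Diffusion covariates are plug-in observed values; latent cross-country
  feedback is not modelled.
* The measurement offset must be chosen consistently between aggregation
  and fitting; the model validates positivity but cannot detect a
  mismatched choice.
* The PF standard error underestimates slightly when weights degenerate;
  use more particles rather than trusting the SE in that regime.
* Model labels F–J beyond the documented ladder are conventions of this
  package; any flag combination can be built explicitly.
* The religion mapping covers only the documented Protestant/Catholic
  country lists and errors on anything else by design.
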