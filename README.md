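# revoquant

Quantitative machinery for estimating historical scientific (and more
broadly cultural) production from per-individual notability indicators,
and for inferring the drivers of its dynamics with partially observed
Markov models and autoregressive linear mixed models.

It is aimed at researchers in cultural evolution, economic history and
digital humanities who work with biography-level indicator tables
(e.g. encyclopedia page length, language coverage and inbound links for
historical scientists) plus country-level environment series (population,
GDP per capita, urbanisation, institutions), and who want to go from raw
indicators to defensible statements about what drove production over
centuries.

## What it computes

**Individual productivity.** Nine per-person indicators (three proxies ×
three language editions) are combined by PCA on their correlation matrix;
the projection on the first principal component is the individual
productivity score. The tail of these scores is summarised by the
continuous-MLE (Hill) estimate of the CCDF exponent,
`alpha_hat = n / Σ log(x_i/xmin)`; Zipf-like data give `alpha ≈ 1`.

**National aggregation.** The National Scientific Product at year *y* is
the summed productivity of everyone reaching peak age (35) in
*[y − 25, y + 25]*. Per-capita series divide by population linearly
interpolated to a 10-year grid and are loess-smoothed over 50-year
windows; growth rates, country shares and robustness splits (top-10% /
bottom-90%, region pooling) are provided.

**Dynamics.** Production follows a latent log-scale process per country
*c* on the decadal grid,

    x[c,t] = mu + rho·x[c,t−1] + beta'·z[c,t] + sigma·eps[c,t]
    log(Y[c,t] + offset) ~ N(x[c,t], tau²)

where the z-scored covariates z are economic development (GDP per
capita), a country's own cumulative past production (vertical
transmission, `Cum`), inverse-squared-distance-weighted neighbour
production (horizontal transmission, `Diff`), its cumulative version
(`Cum_diff`) and a GDP×diffusion interaction. Switching terms on and off
yields a ladder of models (A, B, C, … K) compared by AIC/BIC and
likelihood-ratio tests. The likelihood is evaluated either by a bootstrap
particle filter (generic, supports Student-t innovations) or by the exact
Kalman recursion (linear-Gaussian case); MLE uses derivative-free search
with common random numbers.

**Associations.** Log per-capita production sampled every 50 years is
regressed on environment predictors with a country random intercept and
AR(1) within-country residuals (profile ML), including the joint
Protestantism + GDP model.

A synthetic-data generator with known ground truth (truncated-Pareto
scores, noisy monotone indicators, the canonical panel process) makes the
whole pipeline testable end to end.

## Worked example

```python
import revoquant as rq

cfg = rq.GeneratorConfig(n_individuals=10_000, n_countries=8, seed=1)
bios = rq.simulate_individuals(cfg)
tail = rq.fit_power_law(bios["score"], xmin=cfg.xmin)
print(f"Hill tail exponent: {tail.alpha_hat:.3f}")

truth = rq.ParamVector(mu=0.4, rho=0.6, beta_gdp=0.3,
                       sigma_proc=0.3, tau_obs=0.4)
panel, _ = rq.simulate_panel(cfg, params=truth, spec=rq.model_from_label("C"))
fits = [rq.ProductionDynamics(panel, rq.model_from_label(m)).fit()
        for m in ("B", "C", "D", "E")]
print(rq.compare_models(fits).to_string(index=False))
print(rq.lrt(fits[1], fits[3]))   # does horizontal diffusion add anything?
print(fits[1].summary())
```

Output:

```
Hill tail exponent: 0.993
model      loglik  k        aic        bic  delta_aic  delta_bic
    C -341.918485  5 693.836970 714.270844   0.000000   0.000000
    E -341.819302  6 695.638604 720.159252   1.801634   5.888408
    B -380.681771  4 769.363542 785.710640  75.526572  71.439797
    D -380.617844  5 771.235689 791.669562  77.398719  77.398719
LRTResult(deviance=0.198..., df=1, p=0.656...)
Production dynamics model C
  hypotheses: h1_noise, h2_autoreg, h3_gdp
  likelihood: exact
  loglik -341.918   k 5   n_obs 440
  AIC 693.84   BIC 714.27
  ----------------------------------------
  mu            0.5605  (se 0.1199)
  rho           0.4460  (se 0.1188)
  beta_gdp      0.3756  (se 0.0792)
  sigma_proc    0.3942  (se 0.0880)
  tau_obs       0.3298  (se 0.0917)
```

The data were generated from model C (autoregression + economic
development, no between-country transmission). The comparison table
recovers exactly that: C wins on AIC and BIC, adding horizontal diffusion
(model E) buys a deviance of 0.2 (p = 0.66, not significant), and the
fitted coefficients sit within a standard error or two of the generating
values (rho = 0.6, beta_gdp = 0.3, sigma = 0.3, tau = 0.4).

## Command line

```sh
revoquant all --seed 7 --out run/            # simulate → … → report
revoquant simulate --config cfg.yaml --out run/
```

Stages read and write plain CSV/JSON artifacts; `report` writes a
manifest with SHA-256 hashes so a rerun is verifiably byte-identical.

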