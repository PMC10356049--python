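# smallarea

Small-area disease mapping and health-care accessibility analysis for
city-scale ecological studies.

## The problem

Mortality from acute events such as myocardial infarction varies sharply
*within* cities, but death counts in small administrative units (townships of
~10 000–90 000 residents) are too noisy to map directly, and the role of
access to hospital care in that variation is hard to quantify from raw
counts.  This package implements the full analytical chain used in
small-area cardiovascular epidemiology:

1. **Accessibility** — the enhanced two-step floating catchment area
   (E2SFCA) method with Gaussian distance decay.  Step 1 computes each
   hospital's supply-to-demand ratio within its catchment,
   `R_j = S_j / Σ_i W(t_ij) P_i`; step 2 sums distance-weighted ratios per
   township, `A_i = 1000 · Σ_j W(t_ij) R_j` (supply units per 1000
   population).  The decay kernel is
   `W(t) = [e^{-(t/d0)²/2} − e^{-1/2}] / [1 − e^{-1/2}]` for `t ≤ d0`, 0
   beyond.  PCI-capable and other hospitals can be stratified; beds or
   staffing can serve as supply.
2. **Spatial smoothing** — the Besag–York–Mollié (BYM) model per sex × age
   band × 3-year period: `y_i ~ Poisson(E_i θ_i)`,
   `log θ_i = α + u_i + v_i`, with `u` an intrinsic CAR (ICAR) field on the
   township contiguity graph and `v` i.i.d. Gaussian.  Fitted by
   Metropolis-within-Gibbs MCMC; reported as posterior mean rates per
   100 000/year with 95% credible intervals.
3. **Direct standardization** — stratum rates combined with fixed
   2010-census standard-population weights (age: 82.9 / 14.0 / 3.1 %;
   age-sex: 43.1 / 6.6 / 1.4 % for men and 39.8 / 7.4 / 1.7 % for women),
   applied draw-wise so standardized rates carry credible intervals.
4. **Geographic inequality** — the P90/P10 ratio across townships and, as a
   whole-distribution alternative, the coefficient of variation.
5. **Association models** — a random-intercept linear mixed model of
   township-period mortality levels on accessibility (Models 1–3 with
   risk-factor and socioeconomic adjustment), and OLS of 2007→2018 percent
   changes with the coefficient reported per 10-percentage-point increase in
   accessibility.

Because the registry data such studies use are access-restricted, the
package ships a first-class **synthetic-city generator** (Voronoi townships,
log-normal populations, core-clustered hospitals, Poisson deaths on a
spatially correlated log-risk surface with an optional injected
accessibility effect) so every stage is testable end to end.

## Worked example

```python
from smallarea import (SimulationConfig, generate_city, stratified_accessibility,
                       BYMModel, BYMConfig, decile_ratio)

syn = generate_city(SimulationConfig(n_townships=60, seed=7, n_hospitals=25))
access = stratified_accessibility(syn.city, syn.hospitals)
first = access[(access.period == "2007-2009") & (access.stratum == "total")]["value"]
print("median accessibility 2007-2009: %.2f beds per 1000" % first.median())

model = BYMModel.from_tables(syn.deaths, syn.city, "male", "65-79", "2007-2009")
fit = model.fit(BYMConfig(n_iter=4000, n_burnin=2000, n_chains=2, thin=2, seed=1))
print(fit.summary())
print("P90/P10 of smoothed rates: %.2f" % decile_ratio(fit.rates["rate"]))
```

prints

```
median accessibility 2007-2009: 1.57 beds per 1000
BYM spatial smoothing fit
========================================
townships: 60   draws kept: 2000 (2 chain(s))
converged: True  Rhat[alpha]=1.012 Rhat[tau_u]=1.000 Rhat[tau_v]=1.041
alpha: -6.7890 (95% CI -6.9034, -6.6750)
tau_u: 112.491   tau_v: 29.829
rate per 100k: median 112.52  IQR (105.36, 121.81)
P90/P10 of smoothed rates: 1.35
```

The median accessibility is the beds-per-1000 supply the average township
can reach within the 60-minute catchment.  `alpha ≈ −6.79` is the log
per-person-year baseline risk (`e^{−6.79} ≈ 113/100 000`, matching the
generator's 120/100 000 baseline for men aged 65–79 up to spatial
variation); `tau_u`/`tau_v` are the precisions of the structured and
unstructured random effects; the P90/P10 of 1.35 says the top decile of
smoothed township rates is ~35 % above the bottom decile.

The whole chain — synthesis or ingestion, accessibility, smoothing,
standardization, inequality, changes, association — runs from one config:

```sh
smallarea run --config cfg.yaml          # full pipeline
smallarea synth --out city/ --seed 1     # just the generator
smallarea access --city city/city.geojson --pop city/population.csv \
    --hospitals city/hospitals.csv --out access.csv
smallarea report --outputs smallarea_out/
```

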