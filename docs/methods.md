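# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the known limitations of the `smallarea` package.

## Spatial backbone

Townships are polygons in a projected planar CRS (meters).  Contiguity
defaults to **rook** (shared boundary of positive length), with queen
available; rook is the common choice for areal-unit CAR models, and the
choice matters only for townships meeting at a corner.  The adjacency graph
must be connected — the intrinsic CAR prior is improper on a disconnected
graph — so validation rejects disconnected inputs and names the components.
Geographic (lon/lat) coordinates are rejected rather than reprojected: every
travel-time computation is planar, and a silent reprojection would hide a
units error.

## E2SFCA accessibility

Travel time defaults to straight-line distance at a constant driving speed
(40 km/h), with a 60-minute catchment `d0`.  Both are explicit stand-ins for
a road-network router; a user-supplied townships × hospitals travel-time
matrix bypasses the Euclidean default and is the recommended path for real
data.  The decay kernel is the normalized Gaussian with a hard cutoff
(1 at t=0, continuously to 0 at t=d0); a binary kernel is provided because
it admits closed-form checks (a single global catchment gives every township
`1000·ΣS/ΣP`).

Demand is the township's total population for the period (demand is not
age-stratified).  Hospitals contribute supply only from their first active
period onward.  Stratified surfaces (PCI / non-PCI; beds / personnel)
compute step-1 ratios within the hospital subset but always against the full
population demand, which makes the stratified surfaces exactly additive:
pci + non_pci = total.  Two invariants pin the implementation down:

* conservation — `Σ_i P_i A_i / 1000` equals the summed supply of every
  hospital whose catchment reaches at least one person;
* monotonicity — adding a hospital or beds never lowers any township's value.

A hospital with supply but zero weighted demand in its catchment gets a zero
ratio with a logged warning (no demand, no allocation).

## BYM smoothing

Each sex × age band × 3-year period slice is fitted independently:

    y_i ~ Poisson(E_i θ_i),  log θ_i = α + u_i + v_i,
    u ~ ICAR(τ_u) with Σu = 0,  v_i ~ N(0, τ_v⁻¹),
    τ_u, τ_v ~ Gamma(1, 0.01)

`E_i` is person-years (population × 3); rates are reported per 100 000 per
year.  The Gamma(1, 0.01) hyperpriors are a standard weakly-informative
disease-mapping default and are configurable.  The population-offset form
(rather than internally standardized expected counts) is used because it
reports on the plain mortality scale the rest of the pipeline consumes.

**Sampler.** Metropolis-within-Gibbs: Gaussian random-walk updates for α and
the latent fields, conjugate Gamma updates for the precisions.  Single-site
updates of `u` use the ICAR full conditional (normal around the neighbor
mean with precision `τ_u·deg_i`) and are executed over graph-colour classes:
within a colour class no two areas are adjacent, so the class updates in one
vectorised step without changing the kernel.  After every sweep `u` is
re-centred and its mean folded into α, enforcing the sum-to-zero constraint.
Proposal scales adapt toward a 0.44 acceptance rate during burn-in only.
Defaults (12 000 iterations, half burn-in, 2 chains, thin 2) suit ~300
areas; tests and the packaged pipeline fixtures use shorter chains (500–
4000 iterations) — those lengths were chosen as the smallest at which the
calibration checks below are stable.  Convergence is monitored by split-R̂
on α, τ_u, τ_v with a 1.1 threshold; exceedances flag (and log) the fit
rather than raising, since a flagged fit is still inspectable.  τ_u mixes
slowest; short-chain fixture runs routinely flag it, which is expected and
harmless for the structural tests that use them.

Townships with zero exposure in a slice are excluded from the likelihood,
receive prior-predictive summaries, and are flagged in the output; deaths
with zero exposure are a validation error.

**Calibration (checked by the test suite and acceptance script):** on
100-township cities simulated from the model, 95% credible intervals cover
the true township risks for ≥90% of townships; α is recovered within 3
posterior SDs in ≥95% of 20 replicates; the variance of posterior mean rates
is below the variance of crude rates in every replicate (smoothing must
reduce noise).

## Standardization, changes, inequality

Direct standardization uses fixed 2010-census weights (age 82.9/14.0/3.1 %;
age-sex 43.1/6.6/1.4 % men and 39.8/7.4/1.7 % women).  A missing cell is a
hard error: renormalizing the remaining weights would silently change the
estimand.  Standardization is applied to posterior rate draws cell-wise and
summarized afterwards, so standardized rates carry credible intervals.

Percent change is `100·(end−start)/start`; a zero start has no defined
relative change and propagates as missing (excluded and counted downstream).
The "declined by ≥50 %" boundary is closed (≤ −50).  Quantiles everywhere
use linear interpolation between order statistics; the P90/P10 ratio is
sensitive to this rule at ~300 areas, so it is fixed rather than
configurable.  The coefficient of variation uses the n−1 sample SD.  Both
inequality metrics are computed on posterior mean rates (not draws).

## Association models

Level models: linear mixed model with a township random intercept, REML,
Wald (large-sample normal) intervals; Satterthwaite small-sample corrections
are not attempted.  Accessibility enters in natural units (supply per 1000),
so the coefficient reads per-unit on the per-100 000 outcome scale; mortality
enters on the raw (untransformed) scale.  Period fixed effects are off by
default with a config switch.  If the REML estimate of the between-township
variance hits zero (or the fit fails), the model degenerates to pooled OLS,
which is then used with a logged note — the two estimators coincide exactly
in that case.

Change models: OLS of township percent changes, coefficient rescaled ×10 to
read per 10-percentage-point increase.  Model 2 adjusts for risk-factor
prevalences (levels in the level design, percent changes in the change
design); Model 3 adds baseline socioeconomic levels.  District-level
covariates are assigned to member townships as-is; the only clustering
control is the township random intercept, a documented limitation of the
ecological design.

Calibration: on null synthetic cities (no injected accessibility effect) the
95% Wald interval for the accessibility coefficient covers zero in ~91 of
100 replicates at 60 townships — inside the binomial tolerance around the
nominal 95 %, but consistently a few points anticonservative.  The cause is
heteroscedastic area-level noise (crude standardized rates are far noisier
in small townships) that the homoscedastic mixed model does not weight; this
is a real property of the Wald interval under the study design, not a bug,
and is why the type-I check uses a binomial band rather than an exact 95 %.

## Synthetic-city generator

The generator's defaults are the study conditions; they emulate:

* ~307 contiguous townships as Voronoi cells of uniform points on a 120-km
  square (a regular-grid layout is retained for closed-form oracle tests);
* log-normal township populations, log-mean 10.43 and log-sd 0.82, giving a
  median of ~33 900 and P90/P10 ≈ 8.2 — matching the study setting's printed
  median and decile spread; populations grow 3 % per period;
* population composition fixed to the 2010-census standard weights (sex ×
  three age bands of the 35+ population), so standardization is exercised
  non-trivially;
* 150 hospitals placed with a Gaussian density around the city center
  (`urban_concentration` scales the clustering), log-normal bed counts (few
  large central hospitals, many small), personnel ≈ 1.4 × beds, the largest
  30 % flagged PCI, 60 % active from the first period and the rest opening
  later (so accessibility rises over the study);
* Poisson deaths per stratum with exposure pop × 3 years, baseline rates
  rising with age and higher in men (10/120/500 per 100 000/year for men,
  5/80/450 for women — magnitudes chosen to give period-by-sex death totals
  of order 8000 at 307 townships), a log-risk surface α + u + v with
  u ~ ICAR(τ_u = 10) sampled via the eigendecomposition pseudo-inverse of
  the ICAR precision and v ~ N(0, 1/25), a secular log-trend of −0.15 per
  period (≈ −36 % over the study, the order of the observed declines), and
  an optional injected accessibility effect γ (per supply-per-1000 unit) on
  log risk — γ is a testing device for the association stage, not an
  empirical claim;
* district-blocked covariates on a 4 × 4 grid of districts: risk-factor
  prevalences (higher away from the core, drifting over periods) and
  socioeconomic levels (income and education higher near the core).

Everything is deterministic given the seed; changing only the seed changes
draws but not structure.

What the generator does **not** emulate: road networks (travel time is
Euclidean), migration and age-structured population dynamics, within-
district covariate variation, non-Poisson overdispersion beyond the latent
field, and the real city's geography.  Passing tests therefore demonstrate
the correctness and calibration of the machinery under the stated generative
model, not the reproduction of any real city's estimates.

## Determinism and seeding

All randomness flows through `numpy.random.Generator`.  The pipeline fans
stage seeds out of the global seed by hashing (stage name, index), so stages
are individually re-runnable with identical results; MCMC chains get
independent `SeedSequence` spawns.  Two pipeline runs with the same config
and seed produce byte-identical CSVs (the run manifest carries a config hash
and no timestamps for exactly this reason).

## Known limitations

* Euclidean travel times understate true driving times in cities with
  rivers, ring roads, or congestion; use the travel-time-matrix input for
  real analyses.
* The MCMC sampler is single-site and can mix slowly in τ_u for weakly
  informative slices; the split-R̂ flag should be heeded before reporting.
* Wald intervals for the mixed model are mildly anticonservative under
  area-level heteroscedasticity (see above).
* Inequality metrics on posterior means understate sampling uncertainty in
  the ratio itself; no CI is attached to P90/P10 or CV.
* The ecological design supports area-level conclusions only.
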