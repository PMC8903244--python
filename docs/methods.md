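# Methods

## The joint meta-regression

One record is one published source-apportionment measurement: a city's
annual-mean PM2.5 (µg/m³) and the percentage of it attributed to traffic.
Traffic-related PM2.5 is derived as overall × share/100, so the two
outcomes are algebraically linked and strongly dependent; modelling them
jointly (a two-equation seemingly-unrelated regression on the log scale)
lets each equation borrow strength from the other and yields a posterior
for their residual correlation ρ.

For record i, y_i = (ln traffic, ln overall) ~ MVN(μ_i, Σ) with
μ_ki = η_k + γ_k·X_ki. Assumptions worth stating plainly:

* log-normality of both concentration outcomes given covariates;
* a single shared Σ across all records (no heteroscedasticity by region or
  method);
* no within-city random effect — cities contributing several measurements
  enter as independent rows (the model has no hierarchy over cities, so a
  city's posterior concentration is driven by its covariates, not by
  pooling its own records);
* exchangeability of records given the covariates.

### Priors and sampler

Coefficients and intercepts: independent normal(0, 100) — variance 100,
effectively flat on the log-concentration scale. Precision matrix:
Σ⁻¹ ~ Wishart(R, K) with K = 2 and R = diag(0.01), in the convention where
the prior expectation of Σ⁻¹ is K·R⁻¹ (the WinBUGS `dwish` convention;
this is stated explicitly because the scale-vs-rate ambiguity of the
Wishart is a classic source of silent errors).

Both full conditionals are closed-form, so we use a conjugate Gibbs
sampler rather than a generic MCMC engine:

* **Coefficients | Σ** — all intercepts and slopes of both equations are
  drawn in one joint normal update. With Ω = Σ⁻¹, the precision of the
  stacked coefficient vector is the block matrix [Ω_kl X_kᵀX_l] plus the
  prior precision on the diagonal; the cross-products X_kᵀX_l and X_kᵀy_l
  are computed once before the loop, so each iteration costs one dense
  Cholesky of a 14×14 matrix.
* **Σ⁻¹ | residuals** — Wishart(R + S, K + N) with S the 2×2 residual
  cross-product. Draws use the Gaussian outer-product construction
  (integer degrees of freedom), which is exact and keeps all randomness in
  one `numpy` Generator for reproducibility.

Protocol defaults: 2 chains × 15,000 iterations, 5,000 burn-in, no
thinning (20,000 retained draws). Chains start from overdispersed
coefficient values (prior sd × standard normal) and from the OLS residual
covariance for Σ. Convergence is summarised by the classic Gelman–Rubin
potential scale reduction factor per scalar parameter, flagged above 1.1.
Because the sampler is conjugate and the posterior unimodal, R̂ is
typically below 1.001 after burn-in.

Numerical guards: Σ draws are symmetrised as (Σ+Σᵀ)/2; if the Cholesky of
R + S fails (it should not, R is PD), a 1e-10 ridge is added and the event
counted in the fit log. Rank deficiency of either design matrix is
detected up front via QR and reported with the offending column names.

## Curation rules

* Only urban-site records that report a traffic share are retained (site
  typologies such as industrial or rural are excluded for comparability).
* ln_population = ln(population / 1e6): populations are expressed in
  millions before the log — the only scaling consistent with the
  covariate ranges this generator emulates (mean ≈ −0.13, min ≈ −7).
* Latitude is signed (southern hemisphere negative) and divided by 10.
* post2005 = 1 iff publication year > 2005 (strictly after).
* Location has four levels: North America/Oceania/Japan, NW/W Europe,
  rest of Europe, rest of the world (reference). Japan is grouped with
  North America/Oceania by country override, as a high-income country with
  comparable concentrations, whatever its region label.
* Records with share exactly 0 are dropped with a logged reason (the log
  transform is undefined); records missing population or latitude are
  dropped (complete-case) and logged. Non-positive population or
  concentration, or share outside (0, 100], are hard validation errors
  reported with row numbers — never silently dropped.

## The synthetic-data generator

The generator reads the model forward and emulates the urban records of
the WHO source-apportionment database. Covariate laws (independent across
covariates; the real database's joint law is unknown):

| covariate | law | default |
|---|---|---|
| ln population (millions) | normal | mean −0.13, sd 1.68 (city-level) |
| latitude (°) | normal, truncated to [−55, 70] | mean 30.97, sd 23.61 |
| sea-salt reported | Bernoulli | p = 0.50 (record-level) |
| published after 2005 | Bernoulli | p = 0.742; years U{1987..2005} / U{2006..2014} |
| region | categorical over 12 regions | observed urban frequencies, normalised |

True coefficients default to realistic effect sizes for urban PM2.5
meta-regression (e.g. intercepts 2.54 and 3.63 on the log scale; strong
negative high-income-location effects). Residual scales are not reported
anywhere for this model class, so they are chosen once to make recovery
tests well-conditioned rather than to mimic the real data: sd(ln traffic)
= 0.5, sd(ln overall) = 0.35, ρ = 0.6, i.e. Σ = [[0.25, 0.105], [0.105,
0.1225]].

Rows where the simulated traffic concentration would exceed the overall
concentration are rejection-resampled (not truncated), keeping the MVN law
conditionally intact; the rejection count is recorded in the truth ledger.
At the default parameters the rejection rate is a fraction of a percent,
so the distortion of the nominal MVN law is negligible — but it exists,
which is why model-level symmetry checks can switch the cap off
(`enforce_share_cap=False`). Each dataset ships with a truth ledger (all
generating parameters, per-row latent means, seeds) sufficient to score
recovery externally.

What the generator does **not** emulate: measurement error differences
between apportionment methods (PMF vs CMB), correlations between
covariates, spatial correlation between cities, and the real database's
city-size selection. Passing recovery tests therefore demonstrates the
estimator is correct *under the stated model*, not that the model captures
every feature of the real database.

Master seeds are split into named substreams (covariates, outcomes,
miscellaneous; data vs fit vs IER in the pipeline) via `SeedSequence`
spawning, so stages can be varied independently and every artifact is
reproducible byte for byte from the config seed.

## Per-city inference

A city is represented by the covariates of its most recent record
(configurable to the mean of its records). The back-transform from log
scale is the lognormal **median** exp(μ) by default; exp(μ + Σ_kk/2) (the
lognormal mean) is available as `lognormal_mean`, and the choice is
recorded in the run manifest. The exceedance probability at threshold T
(default 5 µg/m³) is the fraction of posterior draws with
exp(μ₂) − exp(μ₁) ≥ T; a draw exactly at T counts as exceeding. Draws
where traffic exceeds overall keep their negative non-traffic value (they
count as non-exceeding) and are tallied in a warning counter — clamping
them would bias the probability upward invisibly.

## Health impact

RR(pm) = 1 + ϑ(1 − exp(−ω zᵟ)), z = max(0, pm − x). The counterfactual
threshold x is uniform on [2.4, 5.9] µg/m³ and sampled per draw,
independently of (ϑ, ω, δ) unless a supplied draw file provides joint
draws. PAF = 1 − RR(pm_cf)/RR(pm_b) uses posterior-*mean* concentrations
(pm_b = mean overall; pm_cf = pm_b − mean traffic, floored at 0 with a
warning), averaged over the 1000 parameter draws and reported as percent.

The packaged IER parameter laws are **synthetic placeholders, not
GBD/Burnett values** (those are an external input; the interface accepts
them as CSV). Their shapes are qualitatively realistic: shallow saturating
curves for IHD/stroke, steeper ones for COPD/lung cancer/LRI, and a
diabetes-like law that is flat above roughly 20 µg/m³. That flatness is
what produces the *negative returns* mechanism the tests assert: when both
baseline and counterfactual concentrations sit on the flat part, the RR
ratio approaches 1 and the attributable fraction shrinks with increasing
pollution — so for a fixed traffic share, dirtier cities gain a *smaller*
percent mortality reduction for diabetes-like endpoints.

IHD and stroke risks are age-specific; draws carry an age-group label
(default "55–60") that is threaded through, never interpreted.

## Problem sizes and tolerances in the test suite

Unit and property tests run on the packaged 50- and 182-record fixtures
(seeds fixed in `trafficpm.simulate.FIXTURE_SEEDS`). The deeper checks:

* conjugate-oracle agreement with the closed-form normal-normal posterior
  at 10,000 retained draws, within 3 Monte-Carlo standard errors (the
  fixed-Σ draws are exact independent posterior draws);
* full-protocol parameter recovery on the 182-record fixture: all 17
  generating scalars inside 99% credible intervals, ρ within ±0.1;
* interval calibration over 50 replicate datasets of 100 records (one
  chain, 2,000 retained draws each), per-parameter 95% coverage required
  in [0.88, 1.00] — with the truth held at the generator defaults this is
  a frequentist coverage check under diffuse priors, and the band allows
  for its binomial noise at 50 replicates;
* byte-identical pipeline reruns at fixed seed.

Monte-Carlo assertions use 3–4 standard-error tolerances throughout; grid
checks of RR monotonicity use 10,000 points with a 1e-12 slack for
floating-point noise.

## Known limitations

* No within-city pooling: repeated measurements of one city are treated
  as exchangeable rows, and city posteriors come from covariates alone.
* Complete-case handling of missing population/latitude; no imputation.
* The share-cap rejection step makes the generator's effective law very
  slightly different from the nominal MVN (logged, not corrected).
* PAF uses posterior-mean concentrations, so MCMC uncertainty is not
  propagated into the health-impact step (a full-uncertainty crossing of
  concentration draws with IER draws would be a straightforward
  extension but is not the default behaviour anywhere here).
* Robustness to skewness (scale-mixture likelihoods), PM10 outcomes, and
  absolute death counts (which require external baseline mortality rates)
  are out of scope.
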