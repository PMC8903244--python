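# trafficpm

Joint Bayesian meta-regression of urban **overall** and **traffic-related**
PM2.5 concentrations, the per-city probability that air quality would still
exceed the WHO annual guideline if all traffic emissions were removed, and
the resulting health benefit (percent reduction in premature mortality)
computed with integrated exposure–response (IER) functions.

## Who this is for

Air-quality and public-health researchers who have a table of
source-apportionment study results — one row per published measurement of a
city's annual-mean PM2.5 together with the percentage attributed to traffic
— and want to pool them across cities to answer two questions:

1. *If a city eliminated traffic emissions entirely, how likely is it to
   reach the WHO-recommended annual concentration of 5 µg/m³?*
2. *What fraction of mortality from PM2.5-related diseases would that
   eliminate, given the strongly non-linear exposure–response functions?*

Because the underlying database (the WHO source-apportionment database) is
not freely redistributable, the package ships a synthetic-data generator
that emulates it — matched covariate distributions, realistic effect sizes,
and a truth ledger for every dataset — so the entire pipeline is testable
and demonstrable end to end.

## The model

For record *i*, let *y₁ᵢ* = ln(traffic PM2.5) and *y₂ᵢ* = ln(overall
PM2.5), where traffic PM2.5 = overall PM2.5 × (traffic share / 100).
The pair is modelled jointly:

```
(y₁ᵢ, y₂ᵢ) ~ MVN(μᵢ, Σ),   μ_ki = η_k + γ_k · X_ki,   Σ⁻¹ ~ Wishart(R, K)
```

with diffuse normal(0, 100) priors on all intercepts η and coefficients γ,
and K = 2, R = diag(0.01) (prior expectation of Σ⁻¹ is K·R⁻¹). The
covariance Σ carries the dependence between the two outcomes; its implied
correlation ρ = Σ₁₂/√(Σ₁₁Σ₂₂) measures how tightly traffic-related and
overall concentrations move together across cities.

Regressors (traffic equation): ln city population (millions), latitude/10,
sea-salt-reported indicator, published-after-2005 indicator, and location
dummies for North America/Oceania/Japan and NW/W Europe. The overall
equation swaps the post-2005 dummy for a rest-of-Europe dummy.

Both full conditionals are conjugate, so the posterior is sampled with a
Gibbs sampler (joint GLS-form normal update of all coefficients given Σ;
Wishart update of Σ⁻¹ given residuals), two overdispersed chains × 15,000
iterations with 5,000 burn-in by default, checked with the Gelman–Rubin
statistic.

Downstream, for each city *c* with covariates X_c:

* **Exceedance**: per draw, non-traffic PM2.5 = exp(μ₂) − exp(μ₁); the
  exceedance probability is the fraction of draws ≥ 5 µg/m³.
* **Health impact**: RR(pm) = 1 + ϑ(1 − exp(−ω zᵟ)), z = max(0, pm − x),
  with (ϑ, ω, δ) endpoint-specific IER parameters and x ~ U(2.4, 5.9) the
  uncertain no-excess-risk threshold; PAF = 1 − RR(pm_cf)/RR(pm_b) with
  pm_b the posterior-mean overall concentration and pm_cf = pm_b minus the
  posterior-mean traffic concentration, averaged over 1000 parameter draws
  and reported as percent mortality reduction.

## Worked example

```python
import trafficpm as tp
from trafficpm.simulate import load_fixture
from trafficpm.prediction import profiles_from_curated

records, truth = load_fixture("paper_scale")   # 182 synthetic records, 117 cities
kept, _ = tp.filter_records(records)           # urban sites reporting a traffic share
curated, _ = tp.curate(kept)                   # derive traffic PM2.5 + covariates
res = tp.JointMetaRegression.from_dataframe(curated).fit(
    cfg=tp.McmcConfig(seed=20220308))
print(res.summary().round(2))
```

```
                              mean    sd  ci_2.5%  ci_97.5%
traffic:intercept             2.48  0.09     2.30      2.66
traffic:ln_population         0.19  0.02     0.15      0.24
traffic:lat10                 0.07  0.02     0.03      0.10
traffic:sea_salt_reported    -0.35  0.08    -0.49     -0.20
traffic:post2005             -0.29  0.07    -0.43     -0.15
traffic:loc_NA_Oceania_Japan -1.16  0.08    -1.32     -1.00
traffic:loc_NW_W_Europe      -1.81  0.12    -2.04     -1.58
overall:intercept             3.68  0.06     3.55      3.80
overall:ln_population         0.08  0.02     0.05      0.11
overall:lat10                 0.14  0.01     0.11      0.16
overall:sea_salt_reported    -0.36  0.05    -0.46     -0.26
overall:loc_NA_Oceania_Japan -1.12  0.06    -1.23     -1.00
overall:loc_NW_W_Europe      -1.65  0.09    -1.83     -1.48
overall:loc_rest_of_Europe   -0.48  0.06    -0.60     -0.37
sigma_11                      0.23  0.03     0.19      0.29
sigma_12                      0.10  0.02     0.08      0.14
sigma_22                      0.12  0.01     0.10      0.15
```

Each row is a regression coefficient on the log-concentration scale (so
−1.16 for North America/Oceania/Japan means traffic PM2.5 lower by a
factor of e^1.16 ≈ 3.2 relative to the rest of the world, all else equal);
the sigma rows are the residual covariance. The fixture was generated with
known coefficients, and every generating value lies inside its interval.

```python
corr = res.correlation()
# correlation between ln traffic and ln overall PM2.5:
#   0.61 (0.05), 95% CrI [0.51, 0.70]        (generating value: 0.60)

table = res.exceedance_curve(profiles_from_curated(curated), threshold=5.0)
print(table.head(5)[["city", "overall_mean", "nontraffic_mean",
                     "exceedance_probability"]].round(3))
```

```
    city  overall_mean  nontraffic_mean  exceedance_probability
city_080         5.112            4.333                   0.063
city_008         5.133            3.953                   0.015
city_081         6.956            5.624                   0.933
city_097         7.130            6.216                   0.982
city_026         7.503            6.108                   0.980
```

Only the very cleanest cities have an appreciable chance of meeting the
5 µg/m³ guideline after removing traffic; above ~15 µg/m³ overall, the
exceedance probability is essentially 1.

Or from the shell:

```bash
trafficpm simulate --name small --out fixtures/
trafficpm run-all --config config.yaml        # curate → fit → predict → PAF
```

where `config.yaml` needs only `records: fixtures/small_records.csv` — all
other settings default to the reference protocol.

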