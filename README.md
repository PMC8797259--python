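# hiddenpse

Multi-method population size estimation (PSE) for hidden populations —
the estimator toolbox used in hotspot-based surveillance of
hard-to-reach groups such as people who inject drugs (PWID), where no
register exists and direct censuses are impossible.

The package implements, as statsmodels-style model/results objects:

- **Reverse tracking (RTM).** Key informants report a count *Mᵢ* for
  every hotspot; field teams enumerate *Nᵢ* people at visited hotspots.
  With *M = Σ Mᵢ* over all hotspots, each visited hotspot contributes a
  term *Sᵢ = (Nᵢ/Mᵢ)·M*, the city estimate is *S = (1/n) Σ Sᵢ* with
  *Var(S) = Σ(Sᵢ−S)²/(n(n−1))*, and the correction factors *S/M* (and
  its bounds over *M*) turn every key-informant count into a
  per-hotspot size.
- **Unique-object and service multipliers.** A fixed benchmark count
  *n* (objects distributed, unduplicated program clients) divided by
  the survey proportion *p* reporting receipt: *e = n/p*, with a
  design-based cluster-linearized 95% CI for *p* (respondents are
  recruited at hotspots, i.e. clusters) inverted onto *e*.
- **Three-list capture–recapture.** Poisson log-linear models on the
  seven observable cells of the 2×2×2 capture table (all eight
  hierarchical models up to pairwise list-dependence terms, with AIC /
  BIC), plus Bayesian model averaging over the eight decomposable
  graphical models with hyper-Dirichlet priors — the headline estimate
  is the posterior mean of the model-averaged distribution of *N*.
- **Wisdom of the crowds (WOTC).** Medians of respondents' minimum,
  average, and maximum city-size guesses.
- **Anchored-multiplier synthesis.** Each estimate becomes a beta
  distribution on the prevalence scale (mean-constrained quantile
  matching); conjugate pseudo-count pooling with a prior yields a
  consensus, and a variance-adjusted (VA) variant inflates source
  variances by a DerSimonian–Laird heterogeneity estimate before
  pooling.
- **Post-processing.** Winter seasonality correction from monthly
  drop-in-center attendance, male-to-total sex-ratio splitting,
  prevalence computation, lasso-selected Poisson-offset extrapolation
  to unobserved cities, and national aggregation.
- **Synthetic cities.** A generator with fully known truth (hotspot
  allocation, capture histories, benchmarks, crowd guesses, seasonal
  series) so every estimator can be tested for bias and interval
  coverage.

## Worked example

Generate a synthetic city of 1,000 people and run every estimator:

```python
from hiddenpse import (
    TruthConfig, generate_city, run_city, SizeEstimate, Method,
)

cfg = TruthConfig(seed=42)           # true_N = 1000
ds, truth = generate_city(cfg)
prior = SizeEstimate(
    method=Method.PRIOR, city=cfg.city,
    point=1200, lower=800, upper=1800,
    denominator=ds.cities[0].adult_male_pop,
)
run = run_city(ds, cfg.city, prior=prior)
print(run.table().to_string(index=False))
```

```
       method    city subgroup         label  point  lower  upper  denominator  prev_point  prev_lower  prev_upper
        prior simtown     male                 1200    800   1800       100000        1.20        0.80        1.80
          rtm simtown     male                 1009   1000   1052       100000        1.01        1.00        1.05
          uom simtown     male unique object    974    824   1190       100000        0.97        0.82        1.19
           sm simtown     male         prog1   1118    965   1328       100000        1.12        0.96        1.33
crc_loglinear simtown     male  independence    950    894   1019       100000        0.95        0.89        1.02
      crc_dga simtown     male                  951    883   1029       100000        0.95        0.88        1.03
         wotc simtown     male                 1053    795   1311       100000        1.05        0.80        1.31
     anchored simtown     male                 1006    981   1030       100000        1.01        0.98        1.03
  anchored_va simtown     male                 1006    981   1030       100000        1.01        0.98        1.03
```

Each row is one method's estimate of the same 1,000-person population:
point and 95% bounds in persons, plus prevalence per the adult male
denominator. The anchored rows pool the methods with the prior;
because the sources agree here, the variance-adjusted interval
coincides with the unadjusted one (it widens when sources disagree).

Individual estimators are available as model classes, e.g.

```python
from hiddenpse import ReverseTracking
print(ReverseTracking(ds.hotspots).fit().summary())
```

```
Reverse Tracking Method
============================================
City:                simtown
Hotspots visited:    15
KI total (M):        998
Enumerated total:    1000
Estimate S:          1009.2
Var(S):              482.1
95% interval:        (1000.0, 1052.2)
```

A `hiddenpse` command-line tool wraps the library (`simulate`, `rtm`,
`multiplier`, `crc`, `wotc`, `synthesize`, `adjust`, `pipeline`,
`reproduce-study`); see `hiddenpse --help`.

## Reference dataset

`hiddenpse.datasets.afghanistan2019` bundles the published city-level
summary tables of the 2019 eight-city Afghanistan PWID
size-estimation study (adult denominators, 2012 priors, sentinel
monthly series, sex-count tables, and the per-method synthesis rows),
and `hiddenpse.reproduce_study()` recomputes everything those tables
determine: the reverse-tracking worked example, seasonality factors,
sex-ratio arithmetic, prevalences, the seasonality-and-sex-split
chains, a fresh anchored synthesis of the per-method rows, and the
national aggregation.

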