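# Methods

This note records the statistical models the package implements, the
assumptions they lean on, the defaults chosen where the literature
leaves them open, and what the synthetic-data validation does and does
not demonstrate.

## Estimators

### Reverse tracking (RTM)

The estimand is the population attending hotspots. Key-informant
counts *Mᵢ* are treated as a complete census frame (every hotspot is
listed, none double-counted); enumeration *Nᵢ* at the *n* visited
hotspots calibrates them. Each visited hotspot gives a term
*Sᵢ = (Nᵢ/Mᵢ)·M* and the estimate is their unweighted mean with the
usual variance of a mean, *Var(S) = Σ(Sᵢ−S)²/(n(n−1))*. The 95%
interval is the normal approximation *S ± 1.96·√Var(S)* — the
convention symmetric published bounds imply — with the lower bound
floored at the total actually enumerated (an estimate below the number
of people physically counted is incoherent). Unvisited hotspots
contribute to *M* and receive per-hotspot sizes through the correction
factors *S/M*, *lower/M*, *upper/M*; by linearity the per-hotspot
sizes sum back to *(S, lower, upper)* exactly. At least two usable
hotspots are required (one leaves the variance undefined).

### Multipliers

*e = n/p* with the benchmark *n* fixed (no sampling variation — the
program count is an administrative total). The survey proportion *p*
uses one-stage cluster linearization over hotspot totals:
*Var(p) = m/(m−1) · Σ_c (y_c − p·n_c)² / (Σ n_c)²* for *m* clusters,
the standard design-based ratio-estimator variance. Interval bounds
for *p* are truncated to [1/N, 1] so the inverted bounds of *e* stay
finite; *e*'s bounds are *n/p_upper* and *n/p_lower* (monotone
inversion). A single cluster yields a degenerate zero-variance
interval flagged as such rather than an error; *p = 0* is an error
(the multiplier is undefined). A delete-one-cluster jackknife is kept
in the test suite as an independent variance oracle, not used in the
estimator. Recall windows for object or service receipt are treated as
data definitions; no recall-decay correction is applied.

### Three-list capture–recapture

The closed-population 2×2×2 capture table has seven observable cells;
a Poisson log-linear model with occasion main effects and any subset
of the three pairwise interactions is fitted to them by IRLS
(statsmodels GLM, convergence to machine precision), and the
unobserved cell is predicted as exp(intercept). The interval uses a
lognormal delta-method interval on the predicted cell — the unobserved
count is positive and right-skewed, and the log-scale standard error
is exactly the intercept's. AIC is −2ℓ+2k; BIC uses the observed total
as the effective sample size, since the cells partition the observed
individuals. The three-way interaction model is inestimable with one
structurally missing cell, so the hierarchy stops at pairwise terms
(eight models). Fits with an intercept variance above 10⁴ or
|intercept| > 30 are flagged non-converged and excluded from
selection; a table whose margins force perfect separation (e.g. a
single occupied cell) therefore converges in no model and is reported
as such.

The headline estimate is not the lowest-AIC model but the posterior
mean of a Bayesian model average over the eight decomposable graphical
models on three lists (empty, three one-edge, three two-edge,
triangle). Each graph carries a hyper-Dirichlet prior with per-cell
weight δ = 2⁻³ — the conventional "one prior observation spread over
the table" default for this estimator family — and the prior on *N* is
∝ 1/N, the standard scale-invariant choice. For every candidate *N* on
an integer grid starting at the observed total, the marginal
likelihood of the completed table is a ratio of Dirichlet normalizers
over cliques and separators times the multinomial coefficient,
computed in log space with `gammaln` and combined with `logsumexp`.
The grid's upper end defaults to 20× the observed total and doubles
automatically while more than 1% of posterior mass sits at the top
(capped at eight doublings). The credible interval is the central 95%
of the discrete posterior (smallest grid point with CDF ≥ 0.025 /
0.975). Model weights are reported; relabeling the occasions permutes
cells and graphs consistently and leaves the posterior invariant.

### Wisdom of the crowds

Medians of the respondents' minima, averages ((min+max)/2), and maxima,
with even-length medians as the mean of the central pair. The three
medians are not automatically ordered across respondents, so the
reported triple is sorted ascending. Responses missing either bound
are dropped, not imputed.

### Anchored-multiplier synthesis

Each estimate *(point, lower, upper)* over a denominator *D* is
matched to a beta distribution with mean fixed at *point/D* and the
effective sample size α+β chosen by a bounded deterministic search on
log(α+β) ∈ [log 2, log 10⁹] (scipy bounded scalar minimization,
xatol 10⁻¹⁰) minimizing the squared distance of the 2.5%/97.5%
quantiles from *(lower, upper)/D*. Mean-constrained (rather than
mode-constrained) matching makes the pooled posterior mean an exact
pseudo-count-weighted average, so the convex-hull property (consensus
between the prior and source means) holds by construction. A
one-parameter search cannot match two quantiles exactly when the
interval's asymmetry differs from a beta's; fits whose per-quantile
error exceeds a quarter of the interval width are flagged as
inconsistent with any beta of that mean.

Pooling is conjugate: posterior α = prior α + Σ source α, likewise β.
Sources with narrower intervals carry more pseudo-counts and pull the
consensus harder; an empty source list returns the prior unchanged.
The variance-adjusted variant estimates between-source variance τ² by
the DerSimonian–Laird moment estimator on the sources' beta means and
variances, inflates each source's variance by τ², refits each source
by beta moment matching (effective sample size floored at 2 when the
inflated variance is infeasible for a beta), and pools as before. The
prior is not inflated — heterogeneity is a property of the empirical
sources. Because inflation can only reduce each source's pseudo-count,
the VA interval is never narrower than the unadjusted one. It is
**not** guaranteed to contain it: equalizing the source weights shifts
the posterior mean, and on the bundled largest-city fixture the VA
lower bound sits 0.01 percentage points above the unadjusted lower
bound while the interval is four times as wide. Width ordering, not
containment, is the tested invariant.

## Adjustments and extrapolation

**Seasonality.** Per-city factor: mean monthly attendance outside the
collection window over the mean during it. The pooled factor sums the
sentinel cities' series month by month first (requiring a common
collection window) and then averages over calendar months — this
reproduces how a combined sentinel table is constructed — and is
rounded to two decimals for application. The bundled reference profile
applies the fixed published factor 1.10 while also reporting the
recomputed pooled ratio (1.13); both numbers are exposed.

**Sex splitting.** total = male / ratio and female = total − male,
componentwise and unrounded. At presentation time person counts are
rounded half-up and the female count is reported as the difference of
the rounded total and rounded male counts, keeping printed tables
additive. The sex-ratio table averages the two methods' (key
informant, crowd) counts per city, rounded half up, with the overall
row computed from the method column totals rather than the rounded
city rows.

**Prevalence.** 100·count/denominator, reported to two decimals at
presentation time only; all internal arithmetic is unrounded.

**Extrapolation.** Candidate proxies are standardized over the study
cities and entered into an L1-penalized Poisson regression of the male
point estimates with log adult-male population as offset (statsmodels
elastic-net path, intercept unpenalized). The penalty is chosen by
leave-one-out deviance on a seven-point log-spaced grid — with eight
study cities a finer grid adds nothing — and the procedure is fully
deterministic. Selected proxies whose study-city mean ± 2 SD range is
disjoint from the target cities' are dropped (no support for
extrapolating outside the observed proxy range). Three unpenalized
Poisson fits (point, lower, upper responses) predict the target
cities; bound predictions are clamped to bracket the point prediction.
National totals apply the combined urban prevalence to the national
adult population — pure arithmetic, no further modelling.

## The synthetic-city generator

The generator emulates exactly the statistical structure the
estimators assume: a true count allocated to hotspots by a symmetric
Dirichlet-multinomial (concentration 2.0 — a few dominant hotspots,
like observed hotspot-size distributions); key-informant counts equal
to hotspot size times lognormal noise (default sd 0.15 on the log
scale), floored at 1; enumeration as a binomial thinning by an
attendance probability (default 1.0: key informants describe typical
peak attendance and visits occur at peak, so the estimand is the full
hotspot-attending population — smaller values are sensitivity
scenarios in which RTM deliberately targets the attending fraction);
capture histories from an eight-cell joint distribution with the
requested marginals (default 0.3 each), optionally tilted by pairwise
odds multipliers and renormalized, which reproduces the sign of
dependence bias though exact marginals are preserved only at
independence; service receipt as independent Bernoulli (default 0.35);
the object benchmark identical to the first capture occasion so survey
answers and the benchmark are conserved bookkeeping; crowd guesses
lognormal around bias×truth (default bias 1.0, sd 0.4, ±0.25 log
spread between each respondent's min and max); and a cosine seasonal
series peaking in July with amplitude 0.1, collection months
January–March. The default city has 1,000 people across 15 hotspots,
all visited, and an adult male denominator of 100×truth (1%
prevalence).

What the generator does **not** emulate — and hence what passing
recovery tests do not establish for field data: informant frames that
miss hotspots entirely, double-counting of mobile individuals across
hotspots, behavioural dependence between survey participation and
service use, respondent-level heterogeneity in capture probability
(only pairwise list dependence is modelled), recall error in
object/service questions, and any female hotspot structure (women are
generated only as a global ratio, mirroring their near-absence from
hotspot sampling).

## Validation setup

Simulation checks use 500 replicates for bias and coverage (mean
relative bias below 5%, interval coverage at least 90% for RTM, both
multipliers, and independence capture–recapture under the default
conditions), 200 replicates for the dependence sign test, and
20-replicate spot checks elsewhere; oracle equivalences (iterative
proportional fitting, brute-force posterior enumeration, jackknife)
are exact-tolerance comparisons on small tables. The published-study
reproduction recomputes only quantities its printed tables determine;
city-level method estimates whose raw inputs were never published are
validated through the synthetic recovery suite instead.

## Known limitations

- RTM inherits any systematic bias in key-informant counts that does
  not cancel in the ratio (the lognormal-noise model implies a small
  upward bias of order exp(sd²), about 2% at the default sd).
- The clustered CI treats the benchmark as fixed; when the benchmark
  is itself a realized random count the interval is mildly
  conservative for object multipliers (benchmark and survey overlap
  are positively correlated) and mildly anticonservative for service
  multipliers.
- The model-averaged capture–recapture posterior has a heavy right
  tail under near-complete overlap (the 1/N prior decays slowly
  against a barely-informative likelihood); the posterior mode and
  median are then the better summaries.
- The beta-matching objective and variance-adjustment formula of the
  original hosted synthesis calculator are unpublished; this
  implementation's consensus values agree with the published ones to
  about 0.1 percentage points but are not bit-for-bit reproductions.
- Extrapolation assumes the proxy–prevalence relationship learned on
  eight large cities transfers to smaller ones; predictions carry no
  posterior uncertainty beyond the three-model bound scheme.
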