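# Methods

## Data model and preparation

The analysis unit is the **monthly community sample**: all taxa counted at
one station in one calendar month, with one environment record (salinity,
SST, DIN, DIP, silicate) attached per station-month. Preparation applies
four rules, in order:

1. **Within-month averaging.** When a station was sampled on several dates
   in a month, each taxon's monthly abundance is the arithmetic mean over
   those dates, and a taxon counted on one date but absent from another
   date's count list contributes zero for the absent date. The rationale is
   that microscopy counts are censuses of the whole community, not
   presence-only records; treating absence as zero keeps the monthly mean an
   unbiased estimate of the month's standing stock. Environment variables
   are likewise monthly means (missing values ignored).
2. **Genus pooling.** Undetermined congeneric morphotypes (rank `genus`,
   e.g. *Chaetoceros* sp.1 / sp.2) are summed into a single "*Genus* spp."
   unit; determined species stay separate. Total abundance per sample is
   conserved; a pooled unit's per-cell biovolume is the abundance-weighted
   mean of its members.
3. **Station inclusion.** A station is retained only if it has *more than*
   `min_years` (default 10) years in which at least `min_months_per_year`
   (default 8) distinct months were sampled. Mean station salinity — the
   spatial covariate of the whole analysis — is averaged over the months
   that have community samples (not over environment-only months).
4. **Transforms.** DIN and DIP are ln-transformed and silicate
   square-root-transformed before modelling; α richness and α ENS are
   square-root-transformed as responses; sample abundance enters as log10.
   ln of a zero concentration uses a configurable detection-limit floor
   (default 0.01 µmol L⁻¹, logged whenever applied); without a floor it is a
   domain error rather than −inf.

Months are indexed 0 = January … 11 = December everywhere.

## Diversity

Counts in cells L⁻¹ are converted to integer individuals by a configurable
unit (default 1 cell L⁻¹ per individual, rounded half-up); rarefaction
requires integers and reported monitoring abundances are effectively counts
scaled by volume.

**α scale.** Every sample is rarefied to a single global depth: the smallest
scaled sample total in the dataset (floor of the minimum). Samples below the
depth are excluded with a logged warning rather than extrapolated. Expected
richness uses the hypergeometric closed form evaluated with `gammaln`, exact
and overflow-free up to totals ~1e9. Rarefied ENS has no closed form and is
estimated by drawing `reps` multivariate-hypergeometric subsamples (default
500); the mean and its Monte-Carlo standard error are reported. A q = 0
Monte-Carlo path exists and is tested against the closed form; the closed
form is what the pipeline uses for richness. For ENS an optional closed-form
backend, the interpolated Hill-1 estimator exp(E[Hₙ]) with hypergeometric
count probabilities, is provided and tested against the Monte-Carlo route;
Monte-Carlo remains the pipeline default because the interpolation costs
O(S·n) and the depths in monitoring data reach 1e5.

**γ scale.** Station-level diversity is rarefied by *samples*: each of
`reps` (default 500) bootstrap replicates draws `m` monthly samples with
replacement (default 133, or the smallest station sample count when set to
"auto"), pools them taxon-wise, and evaluates richness or ENS on the pool.
Because with-replacement draws include each sample with probability
1 − (1 − 1/S)^m < 1, γ values sit slightly below the all-samples pooled
richness; that is the standardisation, not a bias.

Per-station and per-sample seeds are derived from the run seed by a stable
CRC-32 hash of (seed, station, metric), so results are independent of
iteration order and stations can be recomputed in isolation.

## Seasonality

Within-year z-scores ((x − ȳ)/s per station-year; undefined for years with
fewer than two values or zero spread) describe seasonal shape independent of
level. The annual peak month is the month of the year's maximum raw value,
for years with at least `min_months` (default 8) sampled months; ties break
to the earliest month so the result is order-independent. Peak months are
summarised across years by the circular mean (months mapped to angles on a
12-point wheel; mean direction mapped back to a fractional month in
[0, 12)); a resultant length near zero (balanced peaks, e.g. {January,
July}) makes the mean undefined and raises an error rather than returning an
arbitrary month. Seasonal amplitude is the within-year range (max − min),
averaged over qualifying years — the mean was chosen over the median for
continuity in short records. Peaks and ranges are computed on raw values,
not z-scores.

## Carbon biomass

Per-cell carbon follows the allometric power law C = a·V^b (pg C cell⁻¹,
V in µm³), with coefficients supplied per group through configuration and an
optional second pair above a volume threshold (large diatoms being the usual
case). The packaged default (a = 0.216, b = 0.939) is a generic protist
parameterisation; analyses of real data should set coefficients explicitly.
Measured carbon in the input bypasses the conversion. Group proportions are
computed per sample and averaged per station; their salinity slopes sum to
zero by construction (proportions sum to one at every station and OLS is
linear in the response), which is kept as an invariant check.

## Inference

Station-level relationships use OLS with t-based 95 % CIs and attached
residual diagnostics (Shapiro–Wilk, Breusch–Pagan) for the run log. Two
sensitivity checks accompany each regression: a quadratic term is accepted
only if it both lowers AIC by more than 2 *and* passes the added-term F-test
at p < 0.05, and a flagged outlier station (by default the freshest station)
is refit side-by-side with the full fit.

Monthly-scale models are random-intercept LMMs with station as the grouping
factor, fitted with statsmodels `MixedLM`. The candidate set is exactly the
six hierarchy-respecting subsets of {ln DIN, √silicate, ln DIN × salinity}
that retain mean station-level salinity. Comparisons use **ML** estimation:
REML likelihoods are not comparable across fixed structures. REML is used
only for the random-structure decision, where the fixed part is constant:
the fixed-effects-only REML likelihood is computed in closed form
(l_R = −½[(n−p)(ln 2πσ̂² + 1) + ln|XᵀX|], verified to match `MixedLM`'s REML
likelihood at the zero-variance boundary to 7 decimals) and the random
intercept is kept only when its AIC is lower by more than 2.

Numerical choices:

- AIC counts parameters as fixed effects + variance components + residual
  (p + 2 with the random intercept, p + 1 without).
- Akaike weights are exp(−Δᵢ/2) normalised; a single best model is declared
  only when its AIC is ≥ 2 below all others, otherwise the models within 2
  of the minimum form the reported equivalence set.
- Wald CIs on LMM fixed effects use the normal quantile (±1.959964·SE);
  OLS CIs are t-based. Predictors are not standardised.
- Marginal/conditional r² use the variance of the fixed-effect linear
  predictor over the data as σ²_fixed.
- `MixedLM` optimisers can stall at the zero-variance boundary; the fit
  tries bfgs, lbfgs and powell, keeps the best likelihood, and compares it
  against the closed-form boundary (iid-error) likelihood, which the LMM
  nests. If the boundary matches or beats the optimum, the variance is
  treated as zero: estimates and SEs come from the equivalent fixed-effects
  fit, the boundary parameter stays in the AIC count, and the fit is flagged
  singular. This also makes the zero-variance LMM reproduce OLS exactly.
- One-month-lagged covariates are matched by calendar (January looks up the
  previous December); rows lacking a lagged value are dropped from *both*
  the lagged and unlagged fits so their AICs stay comparable.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, not
ocean physics. Per station s (mean salinity fixed in time — the gradient is
spatial) and month m:

- group abundance shares follow normalised logistics of salinity
  (defaults: cyanobacteria midpoint 10 PSU, slope −0.30; diatoms 15, +0.20;
  dinoflagellates 18, +0.08; other autotrophs 10, +0.05 — dinoflagellates
  rise deliberately more gently than diatoms so the carbon-share gradient,
  which their large cells dominate, preserves the diatom rise);
- each group's station pool is the top k ranks of its pool, k tracking the
  same logistic, so realised richness rises with salinity;
- within-group relative abundances are geometric (θ = 0.85);
- a seasonal factor exp(A·cos(2π(m − μ_s)/12)) with bloom peak
  μ_s = (8.0 − 0.15·sal) mod 12 months puts blooms in late summer at the
  freshest stations and winter–spring at the most marine ones;
- ln DIN *seasonal anomalies* (observed minus the noise-free annual cycle)
  multiply expected abundance by 10^(0.25·c − 0.010·c·(sal − sal̄)): coupling
  to anomalies rather than raw DIN keeps bloom timing governed solely by the
  peak-month parameters while leaving a known DIN effect and DIN × salinity
  interaction for the model-selection layer to find;
- per-taxon counts are lognormal around the expectation (σ = 0.8,
  mean-preserving) with a 0.5 cells L⁻¹ detection limit, which is what makes
  realised richness seasonal;
- environment variables are annual sinusoids plus Gaussian noise, nutrients
  peaking in winter and SST in late summer, so ln DIN and SST are strongly
  negatively correlated as in temperate coastal seas.

Defaults (19 stations, salinity 2.8–35, 19 years, ~255-taxon pool, total
abundance 5e5 cells L⁻¹) mirror the monitoring design the pipeline targets.
The ground-truth object records station salinities, group share curves,
expected biovolume-weighted (~carbon) shares given the drawn cell volumes,
per-station pool sizes, the peak-month parameters and the DIN coefficients.

What the generator does **not** emulate: advection or mixing between
stations, temporal trends or autocorrelation beyond the annual cycle,
grazing or nutrient drawdown feedbacks, taxon-specific phenology within
groups, and observation error in the environment covariates. Passing
recovery tests therefore show the pipeline is correct and unbiased under its
own assumptions — not that those assumptions hold in any particular sea.

A `degrade` operation removes station-months at a configurable rate to
emulate incomplete series, and a flag can enlarge the freshest station's
species pool to exercise the outlier-refit path.

## Problem sizes used in tests

End-to-end recovery tests run 19 stations over 6 years with a ~90-taxon pool
and total abundance 2e4 cells L⁻¹ (20 seeded replicates for the γ-gradient
and peak-timing checks). Selection-consistency studies use 19 stations ×
105 observations (~2000 rows) × 100 replicates per scenario. Rarefaction is
verified against exhaustive enumeration for every count multiset with
N ≤ 12 at every depth, and against vegan's `rarefy` as an independent
implementation. The acceptance script uses 19 stations × 8 years with a
130-taxon pool and 50 selection replicates per scenario.

## Known limitations

- No coverage-based rarefaction or extrapolation beyond observed totals; no
  Hill numbers of order 2.
- The LMM layer fits random intercepts only — no random slopes or temporal
  autocorrelation structures.
- Carbon defaults are one coefficient pair for all groups; per-group values
  (and the large-cell switch) must come from configuration.
- The AIC parameter-counting convention and the ML-for-selection choice are
  stated above; software packages differ on both, so absolute AIC values are
  not comparable across implementations (differences and weights are).
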