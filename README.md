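# saltgrad

Analysis pipeline for nano- and microphytoplankton community structure along
a coastal salinity gradient, built for long-term monthly monitoring data
(cell counts per taxon with salinity, temperature and nutrient covariates).
It answers two questions: how diversity, abundance and group composition
change *spatially* along the gradient, and how they vary *seasonally* — when
blooms peak, whether peak timing shifts with salinity, and which
environmental covariates explain monthly variation. Because real monitoring
databases cannot be redistributed, the package ships a synthetic
monitoring-data generator with known ground truth, so every statistic the
pipeline produces can be checked against the parameters that generated the
data.

## What it computes

**Diversity** (implemented in-package, not delegated):

- α richness and α ENS per monthly sample, rarefied by individuals to the
  smallest sample total. ENS is the effective number of species, the Hill
  number of order 1, `exp(−Σ pᵢ ln pᵢ)`; it obeys the doubling principle.
  Expected rarefied richness uses the hypergeometric closed form
  `E[Sₙ] = Σᵢ 1 − C(N−Nᵢ, n)/C(N, n)` in log-gamma arithmetic; rarefied ENS
  is estimated by multivariate-hypergeometric Monte-Carlo subsampling with a
  reported Monte-Carlo standard error.
- γ richness and γ ENS per station, rarefied by samples: bootstrap
  replicates of *m* monthly samples drawn with replacement are pooled
  taxon-wise and the metric averaged over replicates (defaults m = 133,
  500 replicates).

**Seasonality**: within-year z-scores, annual peak months (0 = January …
11 = December), the circular mean of peak months (unit-vector averaging, so
December and February average to January), and the mean within-year range.

**Biomass composition**: per-cell carbon from cell volume via the power law
`C = a·V^b` (pg C cell⁻¹), summed into four groups (cyanobacteria, diatoms,
dinoflagellates, other autotrophs) with per-sample proportions.

**Inference**: station-level OLS with t-based 95 % CIs, polynomial and
outlier-exclusion sensitivity checks, Pearson correlations with Fisher-z
CIs, VIF screening, and a random-intercept linear mixed model
`yᵢⱼ = β₀ + β′xᵢⱼ + uⱼ + εᵢⱼ` with station as the grouping factor. Six
candidate fixed structures (all hierarchy-respecting subsets of ln DIN,
√silicate and the ln DIN × salinity interaction, always retaining mean
station-level salinity) are compared by ML-based AIC and Akaike weights,
with marginal/conditional r² (`r²m = σ²_fixed / (σ²_fixed + σ²_station +
σ²_resid)`, `r²c` adds σ²_station to the numerator) and Wald CIs on fixed
effects. Covariates can be lagged by one month, with lagged and unlagged
fits constrained to the identical row subset.

## Worked example

```python
import saltgrad as sg
from saltgrad.pipeline import monthly_metrics

cfg = sg.RunConfig(
    synthetic=sg.SyntheticConfig(
        n_stations=8, salinity_range=(3, 35), n_years=6,
        pool_size_by_group={"cyanobacteria": 12, "diatoms": 40,
                            "dinoflagellates": 20, "other_autotrophs": 16},
        total_abundance=2e4, seed=7),
    min_years=4, alpha_reps=30, gamma_reps=100, seed=7,
)
prep = sg.prepare(cfg)
monthly = monthly_metrics(prep, cfg)
q1 = sg.run_question1(cfg, prep=prep, monthly=monthly)
q2 = sg.run_question2(cfg, prep=prep, monthly=monthly)
```

Inspecting the fitted relationships prints:

```text
gamma richness vs salinity: slope 1.24 [1.07, 1.41] per PSU, r2 = 0.982
cyanobacteria biomass share: -0.0006 [-0.0010, -0.0002] per PSU
bloom peak month vs salinity: -0.151 [-0.181, -0.121] months per PSU
best abundance model: log10_abundance ~ salinity + ln_din + sqrt_silicate + ln_din:salinity
  AIC weight 1.000, r2m 0.261, r2c 0.261
```

Reading these: station-scale (γ) richness rises by ≈1.2 rarefied species per
PSU of salinity along the gradient; the cyanobacterial share of carbon
biomass declines toward marine water; bloom peaks arrive ≈0.15 months
earlier per PSU (the generator's true value is −0.15, inside the CI); and
AIC selection picks the model containing the DIN × salinity interaction that
the generator actually simulated.

The same analyses run from the shell:

```sh
saltgrad synth --config config.yaml --out data/ --seed 7
saltgrad all   --config config.yaml --out results/ --seed 7
```

writing tidy CSVs (`gamma_diversity.csv`, `zscores.csv`, `peaks.csv`,
`model_table.csv`, `coefficients.csv`, …) plus a copy of the run config.
Runs are bit-identical given the same config and seed.

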