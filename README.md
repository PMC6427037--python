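# reefbleach

Tools for analysing global coral-bleaching survey data against thermal-stress
history, built for ecologists and biostatisticians working with reef-survey
tables (percent of colonies bleached per site and date) and weekly gridded
sea-surface temperature (SST) products.

The package covers the full analysis chain:

* **Thermal metrics** — per-cell weekly climatology and warmest-month baseline
  (MMM), SST anomalies (SSTA) and thermal-stress anomalies (TSA), their
  frequencies and dispersions, Degree Heating Weeks (DHW, trailing 12-week
  accumulation of ≥1 °C exceedance above the MMM), and the long-run SST trend.
* **A hierarchical Bayesian negative-binomial model** of percent bleaching.
  For survey *i* at site *s* in ecoregion *r*:

  ```
  o_i ~ NegBin(p_i, k),          E(o_i) = p_i,   Var(o_i) = p_i + p_i²/k
  log(p_i) = b₀ + Σ_j γ_j z_ij + a_s
  a_s ~ Normal(R_r, τ),          R_r ~ Normal(g_r, Τ),   g_r = μ + b_div d_r
  ```

  with standardized covariates *z*, site random effects nested in ecoregion
  effects, and a coral species-diversity covariate *d_r* at the ecoregion
  level. The posterior is sampled by an adaptive Metropolis-within-Gibbs
  scheme; effects are classified positive/negative/null by whether their 95%
  credible interval excludes zero.
* **Posterior-predictive checks** tailored to zero-inflated counts: a
  Bayesian P-value for the mean of the non-zero bleaching values, and a
  separate zero check (how often replicates reproduce observed zeros, and how
  much bleaching they predict when they overestimate).
* **Decade-shift analysis** — two-parameter Weibull fits to the SSTs at which
  bleaching was recorded, per decade, compared by a likelihood-ratio test
  (χ², df = 2).
* **Descriptive summaries** — ecoregion z-score maps of the significant
  covariates (≥10-survey rule), absolute-latitude prevalence bands, a
  prevalence-vs-effort Spearman check, and the annual bleaching-probability
  trend with Wilson intervals.
* **A synthetic-world generator** that emulates the study system (weekly SST
  grid with seasonality, warming trend and marine heatwaves; sites nested in
  ecoregions with an equatorial diversity gradient; bleaching drawn from the
  hierarchical model above), so the whole chain is testable end to end.

## Worked example

Run the full pipeline on a synthetic world (12 ecoregions × 20 sites,
20 years of weekly SST) and inspect the fit:

```python
import reefbleach as rb
from reefbleach.config import PipelineConfig, ModelSpec
from reefbleach.pipeline import run_pipeline

cfg = PipelineConfig(
    output_dir="example_out",
    sim=rb.SimConfig(n_ecoregions=12, sites_per_ecoregion=20, weeks=1040,
                     start_year=1988, survey_start_year=1998,
                     n_lat=16, n_lon=32),
    model=ModelSpec(n_chains=3, n_burnin=1500, n_iterations=1500),
    decades=((1998, 2002), (2003, 2007)),
    seed=42,
)
run_pipeline(cfg)
print(open("example_out/fit_summary.txt").read())
```

prints (abridged):

```
Hierarchical negative-binomial bleaching model
  surveys: 658   sites: 240   ecoregions: 12
  chains: 3   burn-in: 1500   iterations: 1500

parameter                        mean       sd     2.5%    97.5%      sign   R-hat
k                               0.504    0.053    0.413    0.616  positive   1.032
gamma_sst_stdev                 0.245    0.075    0.106    0.400  positive   1.010
gamma_tsa                       0.152    0.071    0.007    0.288  positive   1.012
gamma_dhw                       0.294    0.070    0.169    0.445  positive   1.003
gamma_ssta                     -0.014    0.072   -0.153    0.124      null   1.004
gamma_depth                    -0.124    0.072   -0.262    0.025      null   1.002
...
```

Read: accumulated heat stress (DHW) raises the log mean bleaching by ~0.29
standard deviations of DHW per unit (95% CrI [0.17, 0.45], classified
positive); the week-scale anomaly of the survey week itself (SSTA) carries no
signal once the accumulation metrics are in the model. The dispersion
k ≈ 0.5 reflects the strong overdispersion of bleaching counts. The
posterior-predictive checks for the same run (`example_out/ppc.json`)

```
bayes_p_nonzero = 0.566   zero_match_rate = 0.524
overestimate_mean_bleaching = 3.31   overestimate_sd = 4.23
```

say the fit is neither over- nor under-predicting the non-zero mean
(P ≈ 0.5 is ideal), reproduces observed zeros about half the time, and
predicts ~3% bleaching when it misses a zero. The decade comparison
(`example_out/decades.json`) finds no onset-temperature shift between two
adjacent 5-year windows of a 0.02 °C/yr synthetic warming trend
(LRT p = 0.87), as it should.

The same pipeline is available from the shell:

```sh
reefbleach all --seed 42 --out example_out
reefbleach simulate --seed 1 --out sim_out   # or stage by stage
```

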