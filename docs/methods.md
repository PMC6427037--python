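# Methods

This note documents the models, numerical choices and defaults behind
`reefbleach`, and what the synthetic-data experiments do and do not
demonstrate about real reef-survey data.

## The observation model

Percent bleaching per survey is treated as a count on 0–100 and modelled with
a negative binomial in mean/dispersion form: mean `p`, dispersion `k`,
`Var = p + p²/k`. The log link carries the covariate effects and a site
random effect; sites are nested in ecoregions, and the ecoregion mean is a
linear function of (z-scored) coral species diversity:

```
o_i ~ NegBin(p_i, k)
log(p_i) = b0 + Σ_j γ_j z_ij + a_s(i)
a_s ~ N(R_r(s), τ),   R_r ~ N(g_r, Τ),   g_r = μ + b_div d_r
```

Notes and choices:

* **τ and Τ are standard deviations** in every public interface. Precision
  or variance parameterizations common in BUGS-family software are purely
  internal concerns.
* **Support.** The NB has unbounded support while the data live on 0–100.
  Simulated counts are capped at 100 and the model is fitted without a
  truncation correction; this is only coherent while capping is negligible,
  so the generator records the cap rate and the default configurations keep
  it below 0.1% (the shipped defaults produce none). A covariate with a very
  heavy-tailed standardized distribution (DHW is the canonical case: most
  weeks contribute zero, a single prolonged heatwave can sit 10+ sd out)
  must not carry a large coefficient in simulation, or the latent mean
  escapes the percent scale and the cap stops being ignorable. The
  calibration experiments therefore place their strong effects on
  well-behaved covariates and keep DHW's simulated coefficient small or null.
* **Diversity is z-scored across ecoregions** before entering `g_r`. Raw
  species counts are O(100), which would put `b_div` on an unusable scale;
  z-scoring makes it directly comparable with the other standardized effects.
* **Identifiability.** The data see only `b0 + a_s`, and the hierarchy pulls
  `a_s` toward `μ`; with vague priors, `b0` and `μ` are identified only
  through their sum. This mirrors the standard GLMM parameterization and is
  handled in the sampler (below); marginal summaries of `b0` and `μ` are
  wide by construction and should be read jointly.

## Priors

"Vague" is made concrete as: `N(0, 100²)` on `b0`, each `γ_j`, `μ` and
`b_div`; half-Cauchy(0, 2.5) on τ and Τ; Gamma(0.01, rate 0.01) on `k`. All
are configurable through `ModelSpec`. Whether `k` deserves a prior at all is
debatable; it is treated as a free parameter with this vague positive prior.

## Sampler

Adaptive Metropolis-within-Gibbs (`reefbleach.mcmc`):

* random-walk Metropolis on `b0`, each `γ_j`, `log k`, `log τ`, `log Τ`,
  with Robbins–Monro scale adaptation toward 44% acceptance during burn-in
  only (scales are frozen afterwards, keeping the retained chain Markovian);
* all site effects proposed in parallel and accepted per site (conditionally
  independent given the rest); likelihood deltas for mean-only moves use
  `y·Δη − (y+k)·Δlog(k+e^η)`, avoiding gamma-function evaluations;
* exact conjugate Gibbs draws for the ecoregion effects `R_r` and for
  `(μ, b_div)`;
* an exact Gibbs *recentering* move along the likelihood-flat direction
  `(b0+c, a−c, R−c, μ−c)`, which makes the `b0`/`μ` ridge mix instantly
  instead of by random-walk diffusion.

Defaults mirror the published analysis (3 chains, burn-in 4000, 5000
retained iterations); the test suite runs reduced settings (2 chains,
600–1500 iterations) chosen as the smallest that keep the calibration
experiments stable. Convergence is summarized by split-R̂ and effective
sample size (computed with `arviz`); any top-level parameter with R̂ > 1.1
triggers an explicit warning naming it. The variance components τ and Τ are
the slowest movers at short chain lengths — warnings about them at reduced
settings are expected and disappear at the default settings.

Seeding: one integer seed; per-chain generators come from spawned
`SeedSequence` children, so runs are bit-reproducible.

## Thermal metrics

Conventions follow the NOAA Coral Reef Watch / CoRTAD family:

* Climatology = mean per week-of-year over a baseline (≥2 full years;
  default: all pre-survey years). Week 53 folds into week 52. MMM = maximum
  of the long-term calendar-month means.
* SSTA(t) = temp − weekly climatological mean; TSA(t) = temp − MMM.
* DHW = sum of (temp − MMM) over the trailing 12-week window, counting only
  weeks ≥1 °C above the MMM; units °C-weeks. Window and threshold are
  keyword-configurable.
* Frequency metrics count weeks with anomaly ≥1 °C; their "stdev" variants
  are standard deviations of the per-calendar-year exceedance counts.
  Whether running statistics should be lifetime or windowed is genuinely
  open; here they run from the series start to the survey week, and the
  choice is isolated in `metrics_for_survey`.
* Rate of SST change = OLS slope of weekly temperature on fractional years.
* Site-to-cell mapping is nearest-cell-centre, no interpolation. Series with
  more than 5% missing weeks up to the survey date yield flagged (NaN)
  metrics that the preprocessing stage drops.

## Preprocessing

Rows with any missing covariate or an unmapped ecoregion are removed, with
counts and reasons logged. Collinearity pruning is greedy: while any
retained pair has |Pearson r| above the threshold (default 0.65), the member
of the worst pair with the larger mean absolute correlation to everything
else is dropped (ties: later column), and every drop is recorded with its
trigger pair so the retained set is auditable. Standardization uses the
sample sd (n−1); the (mean, sd) pairs are stored so fitted coefficients can
be back-transformed to per-unit effects. Pruning order sensitivity exists in
principle; the permutation behaviour (same retained count) is covered by a
test.

## Posterior-predictive checks

Replicates condition on each posterior draw's site effects (a "mixed" PPC,
matching what a replicated-data monitor inside the MCMC itself would
record). The non-zero check uses the mean over non-zero values as the
discrepancy — an overall-mean Bayesian P-value is uninformative for
zero-inflated data — and the zero check reports the fraction of replicate
values at observed-zero surveys that are zero, plus the mean/sd of positive
replicate values there. A replicate with no non-zero values contributes a
discrepancy of 0. All checks are deterministic given the draws and a
replicate seed. Because the replicates borrow the fitted site effects, the
P-value concentrates near 0.5 under a well-specified model rather than being
uniform; the calibration experiment checks the (0.25, 0.75) containment.

## Decade-shift analysis

"Bleaching onset" is operationalized as any survey with bleaching > 0%; the
analysed quantity is the SST of the survey week at those surveys, split into
two decade windows (defaults 1998–2006 and 2007–2017). Each group gets a
two-parameter Weibull MLE — the shape solves the profile equation
`Σx^c log x / Σx^c − 1/c − mean(log x) = 0` by Brent's method (bracketed,
xtol 1e-12) and the scale follows in closed form — with no location shift,
consistent with the magnitude of the published parameters. The decades are
compared by 2(ll_a + ll_b − ll_pooled) against χ² with 2 df (shape and scale
both free per group). A location-shifted Weibull, or an LRT on a different
likelihood, are defensible alternatives not implemented here.

## The synthetic world

The generator emulates, at desk scale, the structure of a global
reef-survey + weekly-SST study system:

* **SST grid**: latitude-dependent baseline (29 °C at the equator, cooling
  quadratically poleward), sinusoidal seasonal cycle (default amplitude
  2 °C, phase flipped 26 weeks across the equator), linear warming trend
  (default 0.02 °C/yr), weekly white noise (0.25 °C), and sparse positive
  anomaly blocks of 6–16 weeks (marine heatwaves, default 0.4 events per
  cell-year, half-sine profile with |N(0, 1.2 °C)| peaks).
* **World**: ecoregions tile the reef belt (±35°); species diversity
  declines with the band's absolute latitude (~400 at the equator to ~150 at
  the margin), mimicking the equatorial diversity gradient.
* **Surveys**: per-site revisit counts follow 1 + a gamma-Poisson mixture
  with its two moments matched to the published sampling-effort figures
  (mean 2.75 visits, sd 3.17); dates are uniform over the survey period.
* **Bleaching**: drawn from the hierarchical model above with defaults
  b0 = log 1.5, k = 0.5, τ = 0.3, Τ = 0.2, b_div = −0.1, and modest positive
  coefficients on the heat-stress metrics / negative on anomaly variability,
  chosen so that roughly half of surveys record no bleaching (the
  zero-inflated regime of real survey data) and the latent mean stays within
  the percent support.

What passing the synthetic experiments does *not* show about real data: the
generator has no cloud-masked or missing SST, no ocean/land geometry, no
spatial autocorrelation beyond the site/ecoregion hierarchy, no
survey-effort bias toward bleaching events, and its covariates inherit none
of the measurement error of a satellite product. Recovery and calibration
results certify the implementation, not the ecological conclusions.

## Problem sizes used in the shipped experiments

The calibration experiments run 20 replicate studies of ~1000 surveys at 375
sites in 15 ecoregions with 5 covariates, fitted with 2 chains × (1000
burn-in + 1000 retained) iterations; Weibull recovery uses 20,000 samples;
LRT size/power use 1000 and 200 simulations at 500 and 4000 samples per
group. These sizes were chosen as the smallest at which the checks are
stable and well inside their statistical tolerances.
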