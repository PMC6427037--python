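"""Configuration objects for simulation, model fitting and the pipeline.

All configuration is plain dataclasses with YAML round-tripping so that a
pipeline run is fully described by one text file plus one integer seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import yaml


class ConfigurationError(ValueError):
    """Raised when a configuration violates its invariants."""


#: Default standardized-scale coefficients used when simulating bleaching.
#: Signs mirror the qualitative findings of the global analysis: bleaching
#: increases with accumulated heat stress (DHW), thermal-stress-anomaly
#: frequency, survey-time SST and the long-run warming rate, and decreases
#: where week-to-week SST anomalies are more variable.
DEFAULT_TRUE_COEFFICIENTS: dict[str, float] = {
    "dhw": 0.25,
    "tsa_freq": 0.18,
    "ssta_stdev": -0.20,
    "sst_at_survey": 0.10,
    "rate_of_sst_change": 0.15,
}


@dataclass
class SimConfig:
    """Parameters of the synthetic world generator.

    The generative model for bleaching counts is the same hierarchical
    negative-binomial model that is later fitted: on the log scale the mean
    bleaching percentage of observation i is

        log(p_i) = b0 + sum_j gamma_j z_ij + a_s,
        a_s ~ Normal(R_r, site_sd),        R_r ~ Normal(g_r, ecoregion_sd),
        g_r = overall_mean + diversity_effect * d_r,

    with counts o_i ~ NegBin(mean p_i, dispersion k), Var = p + p^2/k,
    capped at 100 (percent scale). ``site_sd`` and ``ecoregion_sd`` are
    standard deviations.
    """

    n_ecoregions: int = 60
    sites_per_ecoregion: int = 56
    weeks: int = 1872                     # 36 years of weekly SST (1982-2017)
    start_year: int = 1982
    survey_start_year: int = 1998         # surveys begin after the climatology baseline
    seasonal_amplitude: float = 2.0       # degC, peak-to-mean seasonal cycle
    warming_trend: float = 0.02           # degC per year
    anomaly_sd: float = 1.2               # degC, scale of marine-heatwave peaks
    anomaly_event_rate: float = 0.4       # heatwave events per cell per year
    noise_sd: float = 0.25                # degC, weekly white noise
    # hierarchical bleaching model (standardized-covariate scale)
    true_coefficients: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRUE_COEFFICIENTS)
    )
    intercept: float = 0.405              # b0 = log(1.5); ~half of surveys bleach
    dispersion: float = 0.5               # k > 0, strong overdispersion
    site_sd: float = 0.30                 # tau
    ecoregion_sd: float = 0.20            # T (upper-case tau in the model)
    diversity_effect: float = -0.10       # b_div, on z-scored species counts
    overall_mean: float = 0.0             # mu
    # survey effort: right-skewed revisit counts, mean 2.75 / sd 3.17
    mean_surveys_per_site: float = 2.75
    sd_surveys_per_site: float = 3.17
    # grid geometry (reef belt)
    n_lat: int = 36
    n_lon: int = 72
    lat_range: tuple[float, float] = (-35.0, 35.0)
    lon_range: tuple[float, float] = (30.0, 210.0)
    depth_range: tuple[float, float] = (2.0, 15.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.weeks < 104:
            raise ConfigurationError(
                "weeks must be >= 104 (two full years) so a climatology exists; "
                f"got {self.weeks}"
            )
        if self.dispersion <= 0:
            raise ConfigurationError("dispersion (k) must be > 0")
        if self.site_sd < 0 or self.ecoregion_sd < 0:
            raise ConfigurationError("site_sd and ecoregion_sd must be >= 0")
        if self.n_ecoregions < 1 or self.sites_per_ecoregion < 1:
            raise ConfigurationError("need at least one ecoregion and one site")
        if self.survey_start_year < self.start_year + 2:
            raise ConfigurationError(
                "survey_start_year must leave >= 2 years of climatology baseline"
            )
        if self.mean_surveys_per_site < 1.0:
            raise ConfigurationError("mean_surveys_per_site must be >= 1")

    @property
    def n_years(self) -> float:
        return self.weeks / 52.0

    @property
    def baseline_years(self) -> tuple[int, int]:
        """Climatology baseline: whole years before surveying starts."""
        return (self.start_year, self.survey_start_year - 1)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["true_coefficients"] = dict(self.true_coefficients)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        d = yaml.safe_load(Path(path).read_text())
        for key in ("lat_range", "lon_range", "depth_range"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class ModelSpec:
    """MCMC settings and priors for the hierarchical bleaching model.

    Defaults mirror the published analysis: 3 chains, burn-in 4000, 5000
    retained iterations. "Flat normal" priors are Normal(0, prior_sd_coefficients)
    on the intercept, covariate coefficients, overall mean and diversity effect;
    the site/ecoregion standard deviations get half-Cauchy priors and the
    negative-binomial dispersion k a vague Gamma prior.
    """

    covariate_names: tuple[str, ...] = ()
    prior_sd_coefficients: float = 100.0
    prior_k_shape: float = 0.01           # Gamma(shape, rate) prior on k
    prior_k_rate: float = 0.01
    prior_sd_scale: float = 2.5           # half-Cauchy scale for tau and T
    n_chains: int = 3
    n_burnin: int = 4000
    n_iterations: int = 5000
    thin: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ConfigurationError("n_chains must be >= 2 for convergence checks")
        if self.n_iterations <= 0 or self.n_burnin < 0:
            raise ConfigurationError("n_iterations must be > 0 and n_burnin >= 0")
        if self.thin < 1:
            raise ConfigurationError("thin must be >= 1")


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration.

    In synthetic mode the three inputs (surveys, SST grid, diversity) are
    generated from ``sim``; otherwise the paths must exist.
    """

    output_dir: str = "reefbleach_out"
    synthetic: bool = True
    survey_csv: str | None = None
    sst_netcdf: str | None = None
    diversity_csv: str | None = None
    sim: SimConfig = field(default_factory=SimConfig)
    model: ModelSpec = field(default_factory=ModelSpec)
    prune_threshold: float = 0.65
    anomaly_threshold: float = 1.0        # degC, SSTA/TSA frequency threshold
    decades: tuple[tuple[int, int], tuple[int, int]] = ((1998, 2006), (2007, 2017))
    min_surveys: int = 10                 # ecoregion inclusion rule
    band_width: float = 5.0               # degrees, latitude profile
    n_ppc_replicates: int = 500
    seed: int = 0

    def validate(self) -> None:
        if not self.synthetic:
            for name, p in (
                ("survey_csv", self.survey_csv),
                ("sst_netcdf", self.sst_netcdf),
                ("diversity_csv", self.diversity_csv),
            ):
                if p is None or not Path(p).exists():
                    raise ConfigurationError(
                        f"non-synthetic mode requires an existing {name}; got {p!r}"
                    )
        lo, hi = self.decades[0][0], self.decades[1][1]
        if lo >= hi:
            raise ConfigurationError("decade ranges must be increasing")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["sim"]["true_coefficients"] = dict(self.sim.true_coefficients)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "sim" in d and isinstance(d["sim"], dict):
            sim = dict(d["sim"])
            for key in ("lat_range", "lon_range", "depth_range"):
                if key in sim and sim[key] is not None:
                    sim[key] = tuple(sim[key])
            d["sim"] = SimConfig(**sim)
        if "model" in d and isinstance(d["model"], dict):
            m = dict(d["model"])
            if "covariate_names" in m and m["covariate_names"] is not None:
                m["covariate_names"] = tuple(m["covariate_names"])
            d["model"] = ModelSpec(**m)
        if "decades" in d:
            d["decades"] = tuple(tuple(x) for x in d["decades"])
        return cls(**d)
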