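"""Synthetic coral-reef world: SST grids, ecoregions, sites and bleaching.

The generator emulates the structure of the real study system — a weekly
~4 km gridded SST product spanning 1982-2017 and a global set of reef survey
sites nested in biogeographic ecoregions — at desk scale, and draws bleaching
observations from the same hierarchical negative-binomial model that the
package later fits. Every stage is deterministic given ``SimConfig.seed``.

SST series per cell = latitude-dependent baseline + sinusoidal seasonal cycle
(phase flipped across hemispheres) + linear warming trend + weekly white
noise + sparse positive anomaly blocks (marine heatwaves).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .config import ConfigurationError, SimConfig
from .thermal import covariates_for_surveys


class GenerationError(RuntimeError):
    """Raised when bleaching observations cannot be generated."""


@dataclass
class SyntheticWorld:
    """A complete simulated study system.

    ``sites`` has one row per site (site_id, ecoregion, latitude, longitude,
    depth_m, cell_lat, cell_lon); ``diversity`` maps ecoregion -> species
    count; ``surveys`` (once generated) has one row per site x date with the
    observed percent bleaching; ``truth`` records the latent effects used to
    generate the observations, for parameter-recovery tests.
    """

    sst: xr.Dataset
    sites: pd.DataFrame
    diversity: pd.DataFrame
    config: SimConfig
    surveys: pd.DataFrame | None = None
    truth: dict = field(default_factory=dict)


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    # named substreams so grid/world/bleaching draws are independently reproducible
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(stream,)))


def gen_sst_grid(config: SimConfig) -> xr.Dataset:
    """Generate the weekly SST grid as an xarray Dataset (lat, lon, time)."""
    if config.weeks < 104:
        raise ConfigurationError("weeks must be >= 104")
    rng = _rng(config, 0)
    nlat, nlon, nt = config.n_lat, config.n_lon, config.weeks
    lat0, lat1 = config.lat_range
    lon0, lon1 = config.lon_range
    lats = lat0 + (np.arange(nlat) + 0.5) * (lat1 - lat0) / nlat
    lons = lon0 + (np.arange(nlon) + 0.5) * (lon1 - lon0) / nlon

    start = np.datetime64(f"{config.start_year}-01-01", "ns")
    time = start + np.timedelta64(7, "D").astype("timedelta64[ns]") * np.arange(nt)
    days = np.arange(nt) * 7.0
    t_years = days / 365.25
    frac_of_year = (pd.DatetimeIndex(time).dayofyear.to_numpy() - 1) / 365.25

    # tropical baseline: warm at the equator, cooling poleward, + cell texture
    baseline = 29.0 - 0.004 * lats[:, None] ** 2 + rng.normal(0.0, 0.3, (nlat, nlon))

    # seasonal cycle peaking in late (local) summer; southern cells 26 weeks out
    peak = np.where(lats >= 0, 0.63, 0.63 - 0.5)[:, None, None]
    seasonal = config.seasonal_amplitude * np.cos(
        2 * np.pi * (frac_of_year[None, None, :] - peak)
    )

    sst = (
        baseline[:, :, None]
        + seasonal
        + config.warming_trend * t_years[None, None, :]
    )
    if config.noise_sd > 0:
        sst = sst + rng.normal(0.0, config.noise_sd, sst.shape)

    if config.anomaly_event_rate > 0 and config.anomaly_sd > 0:
        n_years = config.n_years
        for i in range(nlat):
            for j in range(nlon):
                n_events = rng.poisson(config.anomaly_event_rate * n_years)
                for _ in range(n_events):
                    start_w = int(rng.integers(0, nt))
                    dur = int(rng.integers(6, 16))
                    end_w = min(start_w + dur, nt)
                    peak_amp = abs(rng.normal(0.0, config.anomaly_sd))
                    prof = np.sin(
                        np.pi * (np.arange(end_w - start_w) + 1) / (dur + 1)
                    )
                    sst[i, j, start_w:end_w] += peak_amp * prof

    ds = xr.Dataset(
        {"sst": (("lat", "lon", "time"), sst.astype("float64"))},
        coords={"lat": lats, "lon": lons, "time": time},
        attrs={"units": "degC", "description": "synthetic weekly SST"},
    )
    ds["sst"].attrs["units"] = "degC"
    return ds


def gen_world(config: SimConfig) -> SyntheticWorld:
    """Generate the SST grid, ecoregions, diversity and sites (no surveys).

    Ecoregions tile the reef belt in latitude bands; species diversity
    decreases with absolute latitude, mimicking the equatorial diversity
    gradient. Sites are placed uniformly within their ecoregion's tile.
    """
    sst = gen_sst_grid(config)
    rng = _rng(config, 1)
    lat0, lat1 = config.lat_range
    lon0, lon1 = config.lon_range

    n_eco = config.n_ecoregions
    n_bands = max(1, int(round(np.sqrt(n_eco / 2.0))))
    n_cols = int(np.ceil(n_eco / n_bands))
    band_h = (lat1 - lat0) / n_bands
    col_w = (lon1 - lon0) / n_cols

    eco_rows = []
    site_rows = []
    lats = sst["lat"].values
    lons = sst["lon"].values
    for e in range(n_eco):
        band, col = divmod(e, n_cols)
        blat0 = lat0 + band * band_h
        blon0 = lon0 + col * col_w
        center_lat = blat0 + band_h / 2
        species = max(20, int(round(400.0 - 7.0 * abs(center_lat) + rng.normal(0, 20))))
        eco_rows.append(
            {
                "ecoregion": e,
                "species_count": species,
                "lat_min": blat0,
                "lat_max": blat0 + band_h,
                "lon_min": blon0,
                "lon_max": blon0 + col_w,
            }
        )
        for s in range(config.sites_per_ecoregion):
            slat = rng.uniform(blat0, blat0 + band_h)
            slon = rng.uniform(blon0, blon0 + col_w)
            site_rows.append(
                {
                    "site_id": f"S{e:03d}_{s:03d}",
                    "ecoregion": e,
                    "latitude": slat,
                    "longitude": slon,
                    "depth_m": rng.uniform(*config.depth_range),
                    "cell_lat": float(lats[np.abs(lats - slat).argmin()]),
                    "cell_lon": float(lons[np.abs(lons - slon).argmin()]),
                }
            )

    eco = pd.DataFrame(eco_rows)
    diversity = eco[["ecoregion", "species_count"]].copy()
    sites = pd.DataFrame(site_rows)
    world = SyntheticWorld(sst=sst, sites=sites, diversity=diversity, config=config)
    world.truth["ecoregion_bounds"] = eco
    return world


def _draw_survey_dates(
    world: SyntheticWorld, config: SimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Survey schedule: right-skewed revisit counts matched to the study's
    reported sampling-effort moments (mean 2.75, sd 3.17 visits per site)."""
    m = config.mean_surveys_per_site - 1.0
    v = config.sd_surveys_per_site**2
    time = world.sst["time"].values
    years = pd.DatetimeIndex(time).year.to_numpy()
    eligible = np.where(years >= config.survey_start_year)[0]
    if eligible.size < 12:
        raise ConfigurationError("survey period must cover at least 12 weeks")
    rows = []
    for rec in world.sites.itertuples():
        if m <= 0:
            n = 1
        elif v > m:
            k = m * m / (v - m)
            lam = rng.gamma(k, m / k)
            n = 1 + rng.poisson(lam)
        else:
            n = 1 + rng.poisson(m)
        n = min(n, eligible.size)
        weeks = np.sort(rng.choice(eligible, size=n, replace=False))
        for w in weeks:
            rows.append(
                {
                    "site_id": rec.site_id,
                    "ecoregion": rec.ecoregion,
                    "latitude": rec.latitude,
                    "longitude": rec.longitude,
                    "depth_m": rec.depth_m,
                    "date": pd.Timestamp(time[w]),
                }
            )
    return pd.DataFrame(rows)


def gen_bleaching(
    world: SyntheticWorld,
    config: SimConfig | None = None,
    covariates: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Draw bleaching observations from the hierarchical generative model.

    Draws g_r = mu + b_div * d_r (diversity z-scored across ecoregions),
    R_r ~ Normal(g_r, ecoregion_sd), a_s ~ Normal(R_r, site_sd),
    log(p_i) = b0 + sum_j gamma_j z_ij + a_s with the covariates standardized
    over the generated survey table, then o_i ~ NegBin(mean p_i, size k)
    capped at 100. Returns the survey table (with ``bleaching_pct``) and a
    truth record holding every latent quantity for recovery tests.
    """
    config = config or world.config
    rng = _rng(config, 2)
    surveys = _draw_survey_dates(world, config, rng)
    coef = dict(config.true_coefficients)
    if covariates is None and coef:
        covariates = covariates_for_surveys(
            world.sst, surveys, config.baseline_years
        )
    if covariates is not None:
        join_cols = [
            c for c in covariates.columns
            if c in ("site_id", "date") or c not in surveys.columns
        ]
        tbl = surveys.merge(covariates[join_cols], on=["site_id", "date"], how="left")
    else:
        tbl = surveys.copy()
    Z = np.zeros((len(tbl), len(coef)))
    for j, name in enumerate(coef):
        if name not in tbl.columns:
            raise GenerationError(f"covariate {name!r} not available for surveys")
        x = tbl[name].to_numpy(dtype=float)
        if not np.all(np.isfinite(x)):
            raise GenerationError(f"non-finite values in covariate {name!r}")
        sd = x.std(ddof=1)
        if sd == 0:
            raise GenerationError(f"covariate {name!r} is constant; cannot standardize")
        Z[:, j] = (x - x.mean()) / sd

    # ecoregion level: diversity effect on z-scored species counts
    div = world.diversity.set_index("ecoregion")["species_count"].astype(float)
    if len(div) > 1 and div.std(ddof=1) > 0:
        d_z = (div - div.mean()) / div.std(ddof=1)
    else:
        d_z = div * 0.0
    g_r = config.overall_mean + config.diversity_effect * d_z
    R_r = g_r + config.ecoregion_sd * rng.standard_normal(len(g_r))
    R_r = pd.Series(R_r.to_numpy(), index=g_r.index)

    site_eco = world.sites.set_index("site_id")["ecoregion"]
    a_s = R_r.loc[site_eco.to_numpy()].to_numpy() + config.site_sd * rng.standard_normal(
        len(site_eco)
    )
    a_s = pd.Series(a_s, index=site_eco.index)

    gammas = np.array(list(coef.values()))
    eta = config.intercept + Z @ gammas + a_s.loc[tbl["site_id"]].to_numpy()
    if not np.all(np.isfinite(eta)):
        raise GenerationError("non-finite linear predictor")
    p = np.exp(eta)

    # negative binomial via its gamma-Poisson mixture; cap at the percent scale
    k = config.dispersion
    lam = rng.gamma(k, p / k)
    counts = rng.poisson(lam)
    cap_rate = float(np.mean(counts > 100))
    counts = np.minimum(counts, 100)

    out = tbl.copy()
    out["bleaching_pct"] = counts.astype(int)
    truth = {
        "b0": config.intercept,
        "gamma": coef,
        "k": k,
        "tau": config.site_sd,
        "T": config.ecoregion_sd,
        "mu": config.overall_mean,
        "b_div": config.diversity_effect,
        "d_z": d_z,
        "g_r": g_r,
        "R_r": R_r,
        "a_s": a_s,
        "p": p,
        "Z": Z,
        "covariate_names": list(coef),
        "cap_rate": cap_rate,
    }
    return out, truth


def simulate_world(config: SimConfig | None = None) -> SyntheticWorld:
    """Convenience: generate grid, sites, diversity and bleaching surveys."""
    config = config or SimConfig()
    world = gen_world(config)
    surveys, truth = gen_bleaching(world, config)
    world.surveys = surveys
    world.truth.update(truth)
    return world


def save_sst_netcdf(sst: xr.Dataset, path) -> None:
    """Write the SST grid as classic NetCDF (CF-style time axis)."""
    # scipy backend writes NETCDF3_CLASSIC, readable by any NetCDF tool
    sst.to_netcdf(path, engine="scipy")


def load_sst_netcdf(path) -> xr.Dataset:
    ds = xr.open_dataset(path, engine="scipy")
    return ds.load()
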