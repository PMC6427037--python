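import numpy as np
import pandas as pd
import pytest

import reefbleach as rb


def weekly_series(temps, start="1990-01-01"):
    """Build an SSTSeries from raw weekly temperatures."""
    temps = np.asarray(temps, dtype=float)
    dates = np.datetime64(start, "ns") + np.timedelta64(7, "D").astype(
        "timedelta64[ns]"
    ) * np.arange(len(temps))
    return rb.SSTSeries(dates, temps)


def sinusoid_series(n_weeks, mean=27.0, amplitude=2.0, phase=0.63, start="1990-01-01"):
    dates = np.datetime64(start, "ns") + np.timedelta64(7, "D").astype(
        "timedelta64[ns]"
    ) * np.arange(n_weeks)
    frac = (pd.DatetimeIndex(dates).dayofyear.to_numpy() - 1) / 365.25
    return rb.SSTSeries(dates, mean + amplitude * np.cos(2 * np.pi * (frac - phase)))


@pytest.fixture(scope="session")
def small_config():
    return rb.SimConfig(
        n_ecoregions=6,
        sites_per_ecoregion=10,
        weeks=520,
        start_year=1990,
        survey_start_year=1994,
        n_lat=12,
        n_lon=24,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    """A small but complete synthetic world with surveys and truth."""
    return rb.simulate_world(small_config)


@pytest.fixture(scope="session")
def flat_series():
    return weekly_series(np.full(260, 28.0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def flat_sim_fit():
    """Fit to data simulated with no covariate effects and no hierarchy noise."""
    from reefbleach.config import ModelSpec
    from reefbleach.preprocess import AnalysisTable
    from reefbleach.synthetic import gen_bleaching

    cfg = rb.SimConfig(
        n_ecoregions=5, sites_per_ecoregion=40, weeks=156, start_year=1990,
        survey_start_year=1992, n_lat=10, n_lon=16, true_coefficients={},
        site_sd=0.0, ecoregion_sd=0.0, diversity_effect=0.0,
        intercept=float(np.log(5.0)), dispersion=1.0, seed=21,
    )
    world = rb.gen_world(cfg)
    surveys, _ = gen_bleaching(world, cfg)
    df = surveys.copy()
    df["noise"] = np.random.default_rng(3).normal(0, 1, len(df))  # inert covariate
    table = AnalysisTable(df=df, covariate_names=["noise"])
    model = rb.BleachingModel.from_analysis_table(table, world.diversity)
    spec = ModelSpec(covariate_names=("noise",), n_chains=2, n_burnin=600,
                     n_iterations=600, seed=17)
    return model, spec, model.fit(spec)
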