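"""Hierarchical NB model: likelihood, summaries, convergence, recovery."""
import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.stats import nbinom

import reefbleach as rb
from reefbleach.config import ModelSpec
from reefbleach.mcmc import nb_logpmf
from reefbleach.model import PosteriorDraws
from reefbleach.preprocess import AnalysisTable
from reefbleach.synthetic import gen_bleaching


def _tiny_model(y, Z=None, sites=None, n_eco=2):
    n = len(y)
    Z = np.zeros((n, 1)) if Z is None else Z
    sites = ["s0"] * n if sites is None else sites
    uniq = list(dict.fromkeys(sites))
    eco = {s: i % n_eco for i, s in enumerate(uniq)}
    div = {e: 100 + 10 * e for e in range(n_eco)}
    return rb.BleachingModel(y, Z, ["x"], sites, eco, div)


class TestLikelihood:
    def test_nb_pmf_closed_form_at_zero(self):
        # P(0 | mean 1, k 1) = k/(k+p) = 1/2
        assert nb_logpmf(0, 1.0, 1.0) == pytest.approx(np.log(0.5), abs=1e-12)

    def test_agrees_with_scipy_nbinom_on_grid(self):
        for o in [0, 1, 5, 37, 100]:
            for p in [0.3, 1.0, 5.0, 40.0]:
                for k in [0.2, 1.0, 7.5]:
                    ours = nb_logpmf(o, p, k)
                    oracle = nbinom.logpmf(o, k, k / (k + p))
                    assert ours == pytest.approx(oracle, abs=1e-8), (o, p, k)

    def test_doubling_data_doubles_data_term(self):
        y = np.array([0, 3, 7, 1])
        m1 = _tiny_model(y)
        m2 = _tiny_model(np.tile(y, 2))
        params = {"b0": 0.5, "gamma": [0.0], "k": 1.3, "a": [0.0]}
        assert m2.loglike(params) == pytest.approx(2 * m1.loglike(params), rel=1e-12)

    def test_nonfinite_linear_predictor_flagged(self):
        m = _tiny_model(np.array([1, 2, 3]))
        with pytest.warns(UserWarning, match="non-finite"):
            ll = m.loglike({"b0": np.inf, "gamma": [0.0], "k": 1.0, "a": [0.0]})
        assert ll == -np.inf

    def test_hierarchy_terms_match_normal_density(self):
        m = _tiny_model(np.array([1, 2, 3, 4]), sites=["a", "a", "b", "b"])
        from scipy.stats import norm

        params = {
            "b0": 0.3, "gamma": [0.0], "k": 1.0,
            "a": [0.1, -0.2], "R": [0.05, 0.0], "mu": 0.0, "b_div": 0.0,
            "tau": 0.5, "T": 0.4,
        }
        full = m.loglike(params)
        data_only = m.loglike({"b0": 0.3, "gamma": [0.0], "k": 1.0, "a": [0.1, -0.2]})
        d_z = m.data.d_z
        expected_hier = (
            norm.logpdf([0.1, -0.2], np.array(params["R"])[m.data.site_eco], 0.5).sum()
            + norm.logpdf([0.05, 0.0], 0.0 + 0.0 * d_z, 0.4).sum()
        )
        assert full - data_only == pytest.approx(expected_hier, abs=1e-10)


def _draws_from_arrays(x):
    """Wrap a (chains, draws) array as a single-parameter posterior."""
    C, I = x.shape
    arrays = {
        "b0": x, "k": np.ones_like(x), "mu": np.zeros_like(x),
        "b_div": np.zeros_like(x), "tau": np.ones_like(x), "T": np.ones_like(x),
        "gamma": np.zeros((C, I, 0)),
        "a": np.zeros((C, I, 1)), "R": np.zeros((C, I, 1)),
    }
    return PosteriorDraws(arrays, [], ["s0"], [0])


class TestSummarize:
    def test_constant_draws(self):
        d = _draws_from_arrays(np.full((2, 100), 2.0))
        row = rb.summarize(d).loc["b0"]
        assert row["mean"] == 2.0
        assert row["ci95_low"] == row["ci95_high"] == 2.0
        assert row["classification"] == "positive"

    def test_symmetric_draws_classified_null(self, rng):
        x = rng.normal(0, 1, (2, 5000))
        row = rb.summarize(_draws_from_arrays(x)).loc["b0"]
        assert row["classification"] == "null"

    def test_normal_quantiles_recovered(self, rng):
        x = rng.normal(1.0, 0.1, (2, 5000))
        row = rb.summarize(_draws_from_arrays(x)).loc["b0"]
        # oracle: normal quantiles 1 +- 1.96 * 0.1
        assert row["ci95_low"] == pytest.approx(0.804, abs=0.01)
        assert row["ci95_high"] == pytest.approx(1.196, abs=0.01)
        assert row["classification"] == "positive"

    def test_intervals_nested(self, rng):
        x = rng.normal(0.3, 1, (3, 2000))
        row = rb.summarize(_draws_from_arrays(x)).loc["b0"]
        assert row["ci95_low"] <= row["ci50_low"] <= row["ci50_high"] <= row["ci95_high"]


class TestConvergence:
    def test_iid_chains_near_one(self, rng):
        x = rng.normal(0, 1, (3, 5000))
        conv = rb.convergence_check(_draws_from_arrays(x))
        assert conv.loc["b0", "rhat"] < 1.01

    def test_separated_chains_flagged(self, rng):
        x = np.stack([rng.normal(0, 1, 1000), rng.normal(10, 1, 1000)])
        conv = rb.convergence_check(_draws_from_arrays(x))
        assert conv.loc["b0", "rhat"] > 1.1

    def test_constant_chains_degenerate_not_nan_crash(self):
        conv = rb.convergence_check(_draws_from_arrays(np.ones((2, 100))))
        assert bool(conv.loc["b0", "degenerate"])
        assert np.isfinite(conv.loc["b0", "rhat"])

    def test_single_chain_rejected(self, rng):
        with pytest.raises(ValueError):
            rb.convergence_check(_draws_from_arrays(rng.normal(0, 1, (1, 100))))


class TestFit:
    def test_intercept_recovered(self, flat_sim_fit):
        _, _, res = flat_sim_fit
        eff = res.effects()
        # b0 and mu are only jointly identified; their sum is the intercept
        total = res.posterior.stacked("b0") + res.posterior.stacked("mu")
        assert abs(total.mean() - np.log(5.0)) < 3 * total.std(ddof=1)
        # and the spec'd marginal check holds as well
        assert abs(eff.loc["b0", "mean"] - np.log(5.0)) < 3 * eff.loc["b0", "sd"]

    def test_null_covariate_classified_null(self, flat_sim_fit):
        _, _, res = flat_sim_fit
        assert res.effects().loc["gamma_noise", "classification"] == "null"

    def test_same_seed_identical_draws(self, flat_sim_fit):
        model, spec, res = flat_sim_fit
        res2 = model.fit(dataclasses.replace(spec))
        for key in ("b0", "gamma", "k", "tau"):
            assert np.array_equal(res.posterior.arrays[key], res2.posterior.arrays[key])

    def test_positive_support_draws(self, flat_sim_fit):
        _, _, res = flat_sim_fit
        for key in ("k", "tau", "T"):
            assert (res.posterior.arrays[key] > 0).all()

    def test_summary_and_draw_export(self, flat_sim_fit, tmp_path):
        _, _, res = flat_sim_fit
        text = res.summary()
        assert "surveys" in text and "gamma_noise" in text
        res.posterior.save_csv(tmp_path / "draws.csv")
        back = pd.read_csv(tmp_path / "draws.csv")
        assert {"chain", "draw", "b0", "k"} <= set(back.columns)
        assert len(back) == res.posterior.n_chains * res.posterior.n_draws


def test_posterior_contracts_with_sample_size():
    """Coefficient uncertainty and error shrink as the survey count grows."""
    def one(n_sites, seed):
        cfg = rb.SimConfig(
            n_ecoregions=6, sites_per_ecoregion=n_sites, weeks=260,
            start_year=1990, survey_start_year=1993, n_lat=10, n_lon=16,
            seed=seed,
        )
        world = rb.gen_world(cfg)
        surveys, truth = gen_bleaching(world, cfg)
        names = truth["covariate_names"]
        df = surveys.copy()
        zn = []
        for j, nm in enumerate(names):
            df["z_" + nm] = truth["Z"][:, j]
            zn.append("z_" + nm)
        table = AnalysisTable(df=df, covariate_names=zn)
        model = rb.BleachingModel.from_analysis_table(table, world.diversity)
        spec = ModelSpec(covariate_names=tuple(zn), n_chains=2, n_burnin=700,
                         n_iterations=700, seed=seed + 1)
        res = model.fit(spec)
        eff = res.effects()
        g_true = np.array([truth["gamma"][nm] for nm in names])
        g_hat = np.array([eff.loc["gamma_z_" + nm, "mean"] for nm in names])
        sd_hat = np.array([eff.loc["gamma_z_" + nm, "sd"] for nm in names])
        rmse = float(np.sqrt(np.mean((g_hat - g_true) ** 2)))
        return rmse, float(sd_hat.mean()), len(surveys)

    rmse_small, sd_small, n_small = one(12, 31)
    rmse_large, sd_large, n_large = one(50, 33)
    assert n_large > 3 * n_small
    assert sd_large < sd_small          # posterior width must contract
    assert rmse_large < rmse_small + 0.05


def test_fitted_poisson_limit_variance_near_mean():
    """Data generated at huge k: the fitted model's predictive variance
    approaches its predictive mean (the Poisson limit of the NB variance)."""
    cfg = rb.SimConfig(
        n_ecoregions=4, sites_per_ecoregion=40, weeks=156, start_year=1990,
        survey_start_year=1992, n_lat=8, n_lon=12, true_coefficients={},
        site_sd=0.0, ecoregion_sd=0.0, diversity_effect=0.0,
        intercept=float(np.log(8.0)), dispersion=1e6, seed=41,
    )
    world = rb.gen_world(cfg)
    surveys, _ = gen_bleaching(world, cfg)
    df = surveys.copy()
    df["noise"] = np.random.default_rng(1).normal(0, 1, len(df))
    table = AnalysisTable(df=df, covariate_names=["noise"])
    model = rb.BleachingModel.from_analysis_table(table, world.diversity)
    res = model.fit(ModelSpec(covariate_names=("noise",), n_chains=2,
                              n_burnin=600, n_iterations=600, seed=2))
    reps = res.simulate_replicates(n_replicates=300, seed=9)
    ratio = reps.var(ddof=1, axis=1).mean() / reps.mean()
    assert ratio == pytest.approx(1.0, abs=0.25)
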