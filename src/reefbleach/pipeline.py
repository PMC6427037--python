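"""End-to-end pipeline: simulate -> metrics -> preprocess -> fit -> PPC ->
decade shift -> summaries, with every intermediate artifact written to disk.

Each stage is a function over the output directory, so stages can be run
(and tested) independently; ``run_pipeline`` chains them. All randomness
descends from ``PipelineConfig.seed`` via named substreams.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import decades as decades_mod
from . import summaries as summaries_mod
from .config import PipelineConfig
from .diagnostics import posterior_predictive_check
from .model import BleachingModel, PosteriorDraws, BleachingResults
from .preprocess import build_analysis_table
from .synthetic import simulate_world, save_sst_netcdf, load_sst_netcdf
from .thermal import METRIC_NAMES, covariates_for_surveys

log = logging.getLogger("reefbleach")

SURVEY_COLUMNS = [
    "site_id", "ecoregion", "latitude", "longitude", "depth_m", "date",
    "bleaching_pct",
]
DEFAULT_COVARIATES = list(METRIC_NAMES) + ["abs_latitude", "depth", "year"]


def _substream_seed(seed: int, stream: int) -> int:
    return int(np.random.SeedSequence(seed, spawn_key=(stream,)).generate_state(1)[0] % (2**31))


def _setup_logging(outdir: Path) -> None:
    if any(isinstance(h, logging.FileHandler) for h in log.handlers):
        return
    log.setLevel(logging.INFO)
    fmt = logging.Formatter(
        "%(asctime)s %(levelname)s %(message)s", datefmt="%Y-%m-%dT%H:%M:%S"
    )
    fh = logging.FileHandler(outdir / "pipeline.log")
    fh.setFormatter(fmt)
    log.addHandler(fh)


def stage_simulate(config: PipelineConfig) -> None:
    """Generate the synthetic world and write sst.nc / surveys.csv / diversity.csv."""
    outdir = Path(config.output_dir)
    sim = dataclasses.replace(config.sim, seed=_substream_seed(config.seed, 0))
    world = simulate_world(sim)
    save_sst_netcdf(world.sst, outdir / "sst.nc")
    world.surveys[SURVEY_COLUMNS].to_csv(outdir / "surveys.csv", index=False)
    world.diversity.to_csv(outdir / "diversity.csv", index=False)
    (outdir / "sim_truth.json").write_text(
        json.dumps(
            {
                "b0": world.truth["b0"],
                "gamma": world.truth["gamma"],
                "k": world.truth["k"],
                "tau": world.truth["tau"],
                "T": world.truth["T"],
                "mu": world.truth["mu"],
                "b_div": world.truth["b_div"],
                "cap_rate": world.truth["cap_rate"],
            },
            indent=2,
        )
    )
    log.info(
        "simulated %d surveys at %d sites in %d ecoregions (cap rate %.4f%%)",
        len(world.surveys), sim.n_ecoregions * sim.sites_per_ecoregion,
        sim.n_ecoregions, 100 * world.truth["cap_rate"],
    )


def _load_inputs(config: PipelineConfig) -> tuple[pd.DataFrame, pd.DataFrame, Path]:
    outdir = Path(config.output_dir)
    survey_path = config.survey_csv if not config.synthetic else outdir / "surveys.csv"
    div_path = config.diversity_csv if not config.synthetic else outdir / "diversity.csv"
    surveys = pd.read_csv(survey_path, parse_dates=["date"])
    diversity = pd.read_csv(div_path)
    sst_path = Path(config.sst_netcdf) if not config.synthetic else outdir / "sst.nc"
    return surveys, diversity, sst_path


def stage_metrics(config: PipelineConfig) -> None:
    """Compute thermal covariates for every survey; write covariates.csv."""
    outdir = Path(config.output_dir)
    surveys, _, sst_path = _load_inputs(config)
    sst = load_sst_netcdf(sst_path)
    baseline = config.sim.baseline_years
    cov = covariates_for_surveys(
        sst, surveys, baseline, threshold=config.anomaly_threshold
    )
    cov.to_csv(outdir / "covariates.csv", index=False)
    log.info("computed %d covariate rows (%d metrics)", len(cov), len(METRIC_NAMES))


def stage_preprocess(config: PipelineConfig):
    """Join, filter, prune and standardize; write analysis_table.csv + sidecar."""
    outdir = Path(config.output_dir)
    surveys, diversity, _ = _load_inputs(config)
    cov = pd.read_csv(outdir / "covariates.csv", parse_dates=["date"])
    names = [c for c in DEFAULT_COVARIATES if c in cov.columns]
    table = build_analysis_table(
        surveys, cov, names, diversity=diversity,
        prune_threshold=config.prune_threshold,
    )
    table.save(outdir / "analysis_table.csv", outdir / "preprocess.json")
    log.info(
        "preprocess: %d rows retained (%.1f%% dropped), %d covariates kept, %d pruned",
        len(table.df), 100 * table.dropped_rows["fraction_removed"],
        len(table.covariate_names), len(table.dropped_covariates),
    )
    return table


def _reload_table(config: PipelineConfig):
    outdir = Path(config.output_dir)
    from .preprocess import AnalysisTable

    df = pd.read_csv(outdir / "analysis_table.csv", parse_dates=["date"])
    prov = json.loads((outdir / "preprocess.json").read_text())
    return AnalysisTable(
        df=df,
        covariate_names=prov["covariates"],
        standardization_params={
            k: (v["mean"], v["sd"]) for k, v in prov["standardization"].items()
        },
        dropped_covariates=prov["dropped_covariates"],
        dropped_rows=prov["dropped_rows"],
    )


def stage_fit(config: PipelineConfig) -> BleachingResults:
    """Fit the hierarchical model; write draws, effect summary and summary text."""
    outdir = Path(config.output_dir)
    _, diversity, _ = _load_inputs(config)
    table = _reload_table(config)
    model = BleachingModel.from_analysis_table(table, diversity)
    spec = dataclasses.replace(
        config.model,
        covariate_names=tuple(table.covariate_names),
        seed=_substream_seed(config.seed, 1),
    )
    results = model.fit(spec)
    results.posterior.save_csv(outdir / "draws.csv")
    np.savez_compressed(outdir / "draws_full.npz", **results.posterior.arrays)
    results.effects().to_csv(outdir / "effects.csv")
    (outdir / "fit_summary.txt").write_text(results.summary() + "\n")
    log.info("fit complete:\n%s", results.summary())
    return results


def _reload_results(config: PipelineConfig) -> BleachingResults:
    outdir = Path(config.output_dir)
    _, diversity, _ = _load_inputs(config)
    table = _reload_table(config)
    model = BleachingModel.from_analysis_table(table, diversity)
    arrays = dict(np.load(outdir / "draws_full.npz"))
    posterior = PosteriorDraws(
        arrays=arrays,
        covariate_names=table.covariate_names,
        site_ids=model.data.site_ids,
        eco_ids=model.data.eco_ids,
    )
    spec = dataclasses.replace(
        config.model, covariate_names=tuple(table.covariate_names)
    )
    return BleachingResults(model=model, spec=spec, posterior=posterior)


def stage_ppc(config: PipelineConfig, results: BleachingResults | None = None):
    """Posterior-predictive checks; write ppc.json."""
    outdir = Path(config.output_dir)
    if results is None:
        results = _reload_results(config)
    ppc = posterior_predictive_check(
        results,
        n_replicates=config.n_ppc_replicates,
        seed=_substream_seed(config.seed, 2),
    )
    ppc.to_json(outdir / "ppc.json")
    log.info(
        "PPC: non-zero Bayesian P = %.3f, zero match = %.3f, "
        "overestimate %.2f%% (sd %.2f%%)",
        ppc.bayes_p_nonzero, ppc.zero_match_rate,
        ppc.overestimate_mean_bleaching, ppc.overestimate_sd,
    )
    return ppc


def _raw_joined(config: PipelineConfig) -> pd.DataFrame:
    """Surveys joined with un-standardized covariates (for decades/summaries)."""
    outdir = Path(config.output_dir)
    surveys, _, _ = _load_inputs(config)
    cov = pd.read_csv(outdir / "covariates.csv", parse_dates=["date"])
    join_cols = [c for c in cov.columns if c in ("site_id", "date") or c not in surveys.columns]
    return surveys.merge(cov[join_cols], on=["site_id", "date"], how="inner")


def stage_decades(config: PipelineConfig):
    """Weibull decade-shift analysis; write decades.json + density curves."""
    outdir = Path(config.output_dir)
    df = _raw_joined(config)
    result = decades_mod.decade_shift(df, *config.decades)
    result.to_json(outdir / "decades.json")
    lo = min(result.lrt.fit_a.scale, result.lrt.fit_b.scale) * 0.8
    hi = max(result.lrt.fit_a.scale, result.lrt.fit_b.scale) * 1.1
    pd.concat(
        [
            decades_mod.density_points(result.lrt.fit_a, lo, hi).assign(decade="a"),
            decades_mod.density_points(result.lrt.fit_b, lo, hi).assign(decade="b"),
        ]
    ).to_csv(outdir / "decade_densities.csv", index=False)
    log.info(
        "decades: mean onset SST %.2f -> %.2f degC, LRT stat %.2f, p = %.4g",
        result.mean_onset_a, result.mean_onset_b, result.lrt.stat, result.lrt.p_value,
    )
    return result


def stage_summarize(config: PipelineConfig):
    """Spatial/temporal summaries; writes CSVs and one bundled report.json."""
    outdir = Path(config.output_dir)
    df = _raw_joined(config)
    # keep_default_na: the literal classification "null" must survive the round trip
    effects = pd.read_csv(outdir / "effects.csv", index_col=0, keep_default_na=False)
    sig = [
        p.removeprefix("gamma_")
        for p, row in effects.iterrows()
        if p.startswith("gamma_") and row["classification"] in ("positive", "negative")
    ]
    sig = [c for c in sig if c in df.columns] or [
        c for c in ("dhw", "ssta_stdev") if c in df.columns
    ]
    zs = summaries_mod.ecoregion_zscores(df, sig, min_surveys=config.min_surveys)
    zs.to_csv(outdir / "ecoregion_zscores.csv")
    profile = summaries_mod.latitude_profile(df, band_width=config.band_width)
    profile.to_csv(outdir / "latitude_profile.csv", index=False)
    rho, p = summaries_mod.effort_correlation(profile)
    trend = summaries_mod.annual_trend(df)
    trend.to_csv(outdir / "annual_trend.csv", index=False)
    report = {
        "significant_covariates": sig,
        "spearman_rho_prevalence_vs_effort": rho,
        "spearman_p_value": p,
        "annual_probability_slope_per_year": summaries_mod.trend_slope(trend),
        "n_ecoregions_retained": int(len(zs)),
        "peak_prevalence_band": None,
    }
    nonempty = profile[profile["n_surveys"] > 0]
    if len(nonempty):
        best = nonempty.loc[nonempty["prevalence"].idxmax()]
        report["peak_prevalence_band"] = [float(best["band_low"]), float(best["band_high"])]
    (outdir / "report.json").write_text(json.dumps(report, indent=2))
    log.info("summaries: rho=%.3f (p=%.3f), trend slope %.4f/yr",
             rho, p, report["annual_probability_slope_per_year"])
    return report


_STAGES = (
    ("simulate", stage_simulate),
    ("metrics", stage_metrics),
    ("preprocess", stage_preprocess),
    ("fit", stage_fit),
    ("ppc", stage_ppc),
    ("decades", stage_decades),
    ("summarize", stage_summarize),
)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order; returns a bundle of stage results.

    Any stage failure propagates (non-zero exit under the CLI) with partial
    artifacts preserved and the failing stage named in the log.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    config.to_yaml(outdir / "config.yaml")
    bundle: dict = {}
    results = None
    for name, fn in _STAGES:
        if name == "simulate" and not config.synthetic:
            continue
        t0 = time.perf_counter()
        log.info("stage %s: start (seed %d)", name, config.seed)
        try:
            if name == "ppc":
                bundle[name] = fn(config, results)
            else:
                bundle[name] = fn(config)
            if name == "fit":
                results = bundle[name]
        except Exception:
            log.exception("stage %s: FAILED", name)
            raise
        log.info("stage %s: done in %.1fs", name, time.perf_counter() - t0)
    return bundle
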