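"""Hierarchical Bayesian negative-binomial model of coral bleaching.

The observation model for the percent of colonies bleached at survey i is

    o_i ~ NegBin(mean p_i, dispersion k),      Var(o_i) = p_i + p_i^2 / k,
    log(p_i) = b0 + sum_j gamma_j z_ij + a_s(i),

with standardized covariates z and site random effects a_s nested in
ecoregion effects:

    a_s ~ Normal(R_r(s), tau),   R_r ~ Normal(g_r, T),   g_r = mu + b_div d_r,

where d_r is the (z-scored) coral species diversity of ecoregion r. tau and
T are standard deviations. The model is fitted by MCMC (see ``mcmc``); the
results object carries the posterior draws, credible-interval summaries with
the positive/negative/null sign classification, convergence diagnostics and
posterior-predictive checks.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .config import ModelSpec
from .mcmc import ModelData, nb_logpmf, sample_posterior
from .preprocess import AnalysisTable

TOP_LEVEL_PARAMS = ("b0", "k", "mu", "b_div", "tau", "T")


class ConvergenceWarning(UserWarning):
    pass


@dataclass
class PosteriorDraws:
    """MCMC output: arrays keyed by parameter, shaped (chain, draw, ...)."""

    arrays: dict[str, np.ndarray]
    covariate_names: list[str]
    site_ids: list
    eco_ids: list

    @property
    def n_chains(self) -> int:
        return self.arrays["b0"].shape[0]

    @property
    def n_draws(self) -> int:
        return self.arrays["b0"].shape[1]

    def named_top_level(self) -> dict[str, np.ndarray]:
        """Scalar top-level parameters, gamma expanded by covariate name."""
        out = {p: self.arrays[p] for p in TOP_LEVEL_PARAMS}
        for j, name in enumerate(self.covariate_names):
            out[f"gamma_{name}"] = self.arrays["gamma"][:, :, j]
        return out

    def stacked(self, name: str) -> np.ndarray:
        """Draws for one named parameter with chains concatenated."""
        d = self.named_top_level()
        if name in d:
            return d[name].reshape(-1)
        raise KeyError(name)

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format draws table (top-level parameters only)."""
        rows = {}
        named = self.named_top_level()
        C, I = self.n_chains, self.n_draws
        rows["chain"] = np.repeat(np.arange(C), I)
        rows["draw"] = np.tile(np.arange(I), C)
        for k, v in named.items():
            rows[k] = v.reshape(-1)
        return pd.DataFrame(rows)

    def save_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def summarize(draws: PosteriorDraws, params: list[str] | None = None) -> pd.DataFrame:
    """Posterior means, 50%/95% credible intervals and sign classification.

    An effect is classified positive if its 95% CrI lies entirely above 0,
    negative if entirely below, and null otherwise.
    """
    named = draws.named_top_level()
    params = params or list(named)
    rows = []
    for p in params:
        x = named[p].reshape(-1)
        q = np.quantile(x, [0.025, 0.25, 0.75, 0.975])
        if q[0] > 0:
            cls = "positive"
        elif q[3] < 0:
            cls = "negative"
        else:
            cls = "null"
        rows.append(
            {
                "parameter": p,
                "mean": float(x.mean()),
                "sd": float(x.std(ddof=1)),
                "ci50_low": float(q[1]),
                "ci50_high": float(q[2]),
                "ci95_low": float(q[0]),
                "ci95_high": float(q[3]),
                "classification": cls,
            }
        )
    return pd.DataFrame(rows).set_index("parameter")


def convergence_check(draws: PosteriorDraws) -> pd.DataFrame:
    """Split-R-hat and effective sample size per top-level parameter.

    Constant chains are flagged (``degenerate=True``) rather than reported
    as NaN failures.
    """
    import arviz as az

    if draws.n_chains < 2:
        raise ValueError("convergence diagnostics need >= 2 chains")
    named = draws.named_top_level()
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for p, x in named.items():
            degenerate = bool(np.allclose(x, x.reshape(-1)[0]))
            if degenerate:
                rhat = 1.0
                ess = float("nan")
            else:
                ds = az.convert_to_dataset(np.ascontiguousarray(x))
                rhat = float(az.rhat(ds)["x"].values)
                ess = float(az.ess(ds)["x"].values)
            rows.append(
                {"parameter": p, "rhat": rhat, "ess": ess, "degenerate": degenerate}
            )
    return pd.DataFrame(rows).set_index("parameter")


class BleachingModel:
    """The hierarchical negative-binomial bleaching model, bound to data.

    Parameters
    ----------
    y : array of counts (percent bleached, 0..100) per survey.
    Z : (n, J) standardized covariate matrix.
    covariate_names : names of the J columns.
    sites : site identifier per survey (length n).
    site_ecoregions : mapping site id -> ecoregion id.
    diversity : mapping ecoregion id -> species count. Z-scored internally
        before entering the ecoregion regression g_r = mu + b_div d_r.
    """

    def __init__(self, y, Z, covariate_names, sites, site_ecoregions, diversity):
        y = np.asarray(y, dtype=int)
        Z = np.asarray(Z, dtype=float)
        if y.ndim != 1 or Z.shape[0] != len(y):
            raise ValueError("y and Z must align (one row per survey)")
        if not np.all(np.isfinite(Z)):
            raise ValueError("Z contains non-finite values; preprocess first")
        sites = pd.Series(sites)
        site_ids = list(pd.unique(sites))
        site_pos = {s: i for i, s in enumerate(site_ids)}
        site_idx = sites.map(site_pos).to_numpy()

        eco_of_site = [site_ecoregions[s] for s in site_ids]
        eco_ids = list(pd.unique(pd.Series(eco_of_site)))
        eco_pos = {e: i for i, e in enumerate(eco_ids)}
        site_eco = np.array([eco_pos[e] for e in eco_of_site])

        missing = [e for e in eco_ids if e not in diversity]
        if missing:
            raise ValueError(f"no diversity entry for ecoregion(s) {missing}")
        d = np.array([float(diversity[e]) for e in eco_ids])
        sd = d.std(ddof=1) if len(d) > 1 else 0.0
        d_z = (d - d.mean()) / sd if sd > 0 else np.zeros_like(d)

        self.data = ModelData(
            y=y,
            Z=Z,
            covariate_names=list(covariate_names),
            site_idx=site_idx,
            site_ids=site_ids,
            site_eco=site_eco,
            eco_ids=eco_ids,
            d_z=d_z,
        )

    @classmethod
    def from_analysis_table(
        cls,
        table: AnalysisTable,
        diversity: pd.DataFrame | dict,
        y_col: str = "bleaching_pct",
        site_col: str = "site_id",
        eco_col: str = "ecoregion",
    ) -> "BleachingModel":
        df = table.df
        if isinstance(diversity, pd.DataFrame):
            diversity = dict(
                zip(diversity["ecoregion"], diversity["species_count"])
            )
        site_eco = (
            df[[site_col, eco_col]].drop_duplicates().set_index(site_col)[eco_col]
        )
        return cls(
            y=df[y_col].to_numpy(),
            Z=df[table.covariate_names].to_numpy(),
            covariate_names=table.covariate_names,
            sites=df[site_col].to_numpy(),
            site_ecoregions=site_eco.to_dict(),
            diversity=diversity,
        )

    # ------------------------------------------------------------------
    def loglike(self, params: dict) -> float:
        """Joint log density of the data and hierarchy at given parameters.

        Sum of the NB log-pmf over observations (mean exp(b0 + Z gamma + a),
        size k) plus the normal log densities of the site and ecoregion
        effects. Returns -inf (with a warning) for a non-finite linear
        predictor or out-of-support variance parameters.
        """
        d = self.data
        k = float(params["k"])
        tau = float(params.get("tau", 0.0))
        T = float(params.get("T", 0.0))
        if k <= 0:
            return -np.inf
        a = np.asarray(params["a"], dtype=float)
        eta = float(params["b0"]) + d.Z @ np.asarray(params["gamma"], float) + a[d.site_idx]
        if not np.all(np.isfinite(eta)):
            warnings.warn("non-finite linear predictor in loglike")
            return -np.inf
        ll = float(nb_logpmf(d.y, np.exp(eta), k).sum())
        if "R" in params:
            R = np.asarray(params["R"], dtype=float)
            if tau <= 0 or T <= 0:
                return -np.inf
            ll += float(norm.logpdf(a, R[d.site_eco], tau).sum())
            g = float(params.get("mu", 0.0)) + float(params.get("b_div", 0.0)) * d.d_z
            ll += float(norm.logpdf(R, g, T).sum())
        return ll

    def fit(self, spec: ModelSpec | None = None, **kwargs) -> "BleachingResults":
        """Sample the posterior by adaptive Metropolis-within-Gibbs.

        Emits a ``ConvergenceWarning`` naming any top-level parameter with
        split-R-hat above 1.1; never fails silently.
        """
        if spec is None:
            spec = ModelSpec(covariate_names=tuple(self.data.covariate_names), **kwargs)
        draws = sample_posterior(self.data, spec)
        posterior = PosteriorDraws(
            arrays=draws,
            covariate_names=self.data.covariate_names,
            site_ids=self.data.site_ids,
            eco_ids=self.data.eco_ids,
        )
        results = BleachingResults(model=self, spec=spec, posterior=posterior)
        conv = results.convergence()
        bad = conv.index[conv["rhat"] > 1.1].tolist()
        if bad:
            warnings.warn(
                f"possible non-convergence (R-hat > 1.1) for: {', '.join(bad)}",
                ConvergenceWarning,
            )
        return results

    def simulate(
        self,
        b0: float,
        gamma: np.ndarray,
        a: np.ndarray,
        k: float,
        rng: np.random.Generator,
        cap: int = 100,
    ) -> np.ndarray:
        """Draw one replicate dataset at the given parameters (counts, capped)."""
        d = self.data
        eta = b0 + d.Z @ np.asarray(gamma, float) + np.asarray(a, float)[d.site_idx]
        p = np.exp(eta)
        lam = rng.gamma(k, p / k)
        return np.minimum(rng.poisson(lam), cap)


@dataclass
class BleachingResults:
    """Fitted-model container: draws, summaries, diagnostics, simulation."""

    model: BleachingModel
    spec: ModelSpec
    posterior: PosteriorDraws
    _effects: pd.DataFrame | None = field(default=None, repr=False)

    def effects(self) -> pd.DataFrame:
        """Posterior summary with the positive/negative/null classification."""
        if self._effects is None:
            self._effects = summarize(self.posterior)
        return self._effects

    def convergence(self) -> pd.DataFrame:
        return convergence_check(self.posterior)

    def summary(self) -> str:
        """Human-readable fit summary table."""
        eff = self.effects()
        conv = self.convergence()
        d = self.model.data
        lines = [
            "Hierarchical negative-binomial bleaching model",
            f"  surveys: {d.n}   sites: {d.n_sites}   ecoregions: {d.n_eco}",
            f"  chains: {self.spec.n_chains}   burn-in: {self.spec.n_burnin}"
            f"   iterations: {self.spec.n_iterations}",
            "",
            f"{'parameter':<28}{'mean':>9}{'sd':>9}{'2.5%':>9}{'97.5%':>9}"
            f"{'sign':>10}{'R-hat':>8}",
        ]
        for p, row in eff.iterrows():
            rhat = conv.loc[p, "rhat"]
            lines.append(
                f"{p:<28}{row['mean']:>9.3f}{row['sd']:>9.3f}"
                f"{row['ci95_low']:>9.3f}{row['ci95_high']:>9.3f}"
                f"{row['classification']:>10}{rhat:>8.3f}"
            )
        return "\n".join(lines)

    # -- posterior predictive ------------------------------------------
    def simulate_replicates(self, n_replicates: int = 500, seed: int = 0) -> np.ndarray:
        """Replicate datasets, one per (evenly thinned) posterior draw.

        Site effects are taken from each posterior draw (a "mixed"
        posterior-predictive replicate, conditioning on the fitted sites).
        """
        rng = np.random.default_rng(seed)
        arr = self.posterior.arrays
        C, I = arr["b0"].shape
        total = C * I
        n_replicates = min(n_replicates, total)
        idx = np.linspace(0, total - 1, n_replicates).astype(int)
        b0 = arr["b0"].reshape(-1)[idx]
        gamma = arr["gamma"].reshape(total, -1)[idx]
        k = arr["k"].reshape(-1)[idx]
        a = arr["a"].reshape(total, -1)[idx]
        reps = np.empty((n_replicates, self.model.data.n), dtype=int)
        for i in range(n_replicates):
            reps[i] = self.model.simulate(b0[i], gamma[i], a[i], k[i], rng)
        return reps

    def ppc(self, n_replicates: int = 500, seed: int = 0):
        from .diagnostics import posterior_predictive_check

        return posterior_predictive_check(self, n_replicates=n_replicates, seed=seed)

    # -- plotting -------------------------------------------------------
    def plot_effects(self, ax=None, params: list[str] | None = None):
        """Forest plot of covariate effects: mean, 50% and 95% CrIs, with
        positive effects red, negative blue and null white."""
        import matplotlib.pyplot as plt

        eff = self.effects()
        if params is None:
            params = [p for p in eff.index if p.startswith("gamma_") or p == "b_div"]
        eff = eff.loc[params]
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 0.4 * len(eff) + 1))
        colors = {"positive": "tab:red", "negative": "tab:blue", "null": "white"}
        ypos = np.arange(len(eff))[::-1]
        for y, (p, row) in zip(ypos, eff.iterrows()):
            ax.plot([row["ci95_low"], row["ci95_high"]], [y, y], "k-", lw=1)
            ax.plot([row["ci50_low"], row["ci50_high"]], [y, y], "k-", lw=3)
            ax.plot(
                row["mean"], y, "o",
                color=colors[row["classification"]],
                markeredgecolor="k", markersize=8, zorder=3,
            )
        ax.axvline(0, color="grey", lw=0.8, ls="--")
        ax.set_yticks(ypos)
        ax.set_yticklabels(eff.index)
        ax.set_xlabel("standardized effect on log mean bleaching")
        return ax
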