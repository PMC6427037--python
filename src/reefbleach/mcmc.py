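"""Adaptive Metropolis-within-Gibbs sampler for the hierarchical NB model.

The posterior is the one defined by the bleaching model: a negative-binomial
likelihood with log link on the survey counts, site random effects a_s nested
in ecoregion effects R_r, an ecoregion-level diversity regression
g_r = mu + b_div * d_r, vague normal priors on location parameters,
half-Cauchy priors on the site/ecoregion standard deviations (tau, T) and a
vague Gamma prior on the dispersion k.

Update scheme per iteration:

* random-walk Metropolis on b0, each gamma_j, log k, log tau, log T
  (Robbins-Monro scale adaptation toward 44% acceptance during burn-in only,
  frozen afterwards so the retained chain is Markovian);
* all site effects a_s proposed in parallel and accepted per site (their
  conditional likelihood contributions are independent given the rest);
* exact conjugate Gibbs draws for the R_r vector and for (mu, b_div);
* an exact Gibbs "recentering" move along the likelihood-flat direction
  (b0 + c, a - c, R - c, mu - c): with vague priors on b0 and mu their sum is
  what the data identify, and without this move a coordinate sampler creeps
  along the ridge.

Likelihood deltas for eta-only moves avoid gammaln entirely:
  d loglik = y * d_eta - (y + k) * d log(k + exp(eta)).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .config import ModelSpec

_ADAPT_BATCH = 25
_TARGET_ACC = 0.44


@dataclass
class ModelData:
    """Design arrays for the sampler (all index-encoded)."""

    y: np.ndarray            # (n,) counts, 0..100
    Z: np.ndarray            # (n, J) standardized covariates
    covariate_names: list[str]
    site_idx: np.ndarray     # (n,) -> 0..S-1
    site_ids: list
    site_eco: np.ndarray     # (S,) -> 0..E-1
    eco_ids: list
    d_z: np.ndarray          # (E,) z-scored diversity

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def n_sites(self) -> int:
        return len(self.site_eco)

    @property
    def n_eco(self) -> int:
        return len(self.d_z)


def nb_logpmf(y, mean, k):
    """Negative-binomial log-pmf in mean/dispersion form (Var = m + m^2/k)."""
    y = np.asarray(y, dtype=float)
    mean = np.asarray(mean, dtype=float)
    return (
        gammaln(y + k)
        - gammaln(k)
        - gammaln(y + 1)
        + k * np.log(k / (k + mean))
        + y * np.log(mean / (k + mean))
    )


def _half_cauchy_logpdf(x: float, scale: float) -> float:
    if x <= 0:
        return -np.inf
    return float(np.log(2.0 / (np.pi * scale * (1.0 + (x / scale) ** 2))))


def _data_loglik(y, eta, k) -> float:
    le = np.log(k + np.exp(eta))
    return float(
        np.sum(gammaln(y + k)) - len(y) * gammaln(k) + len(y) * k * np.log(k)
        + np.dot(y, eta) - np.dot(y + k, le)
    )


class _Chain:
    def __init__(self, data: ModelData, spec: ModelSpec, rng: np.random.Generator):
        self.d = data
        self.spec = spec
        self.rng = rng
        n, J = data.n, data.Z.shape[1]
        y = data.y.astype(float)
        self.y = y
        # overdispersed but sane initial values
        self.b0 = float(np.log(y.mean() + 0.1) + rng.normal(0, 0.2))
        self.gamma = rng.normal(0, 0.05, J)
        self.k = float(np.exp(rng.normal(0, 0.2)))
        self.a = np.zeros(data.n_sites)
        self.R = np.zeros(data.n_eco)
        self.mu = 0.0
        self.b_div = 0.0
        self.tau = float(0.3 * np.exp(rng.normal(0, 0.2)))
        self.T = float(0.3 * np.exp(rng.normal(0, 0.2)))
        # cached state
        self.eta = self.b0 + data.Z @ self.gamma + self.a[data.site_idx]
        self.le = np.log(self.k + np.exp(self.eta))
        self.sum_y = float(y.sum())
        self.yZ = y @ data.Z            # (J,) for fast gamma deltas
        self.site_counts = np.bincount(data.site_eco, minlength=data.n_eco)
        # proposal scales
        self.s_b0 = 0.1
        self.s_gamma = np.full(J, 0.05)
        self.s_k = 0.15
        self.s_tau = 0.3
        self.s_T = 0.3
        self.s_a = np.full(data.n_sites, 0.3)
        self._acc = {"b0": 0, "k": 0, "tau": 0, "T": 0}
        self._acc_gamma = np.zeros(J)
        self._acc_a = np.zeros(data.n_sites)
        self._batch = 0
        self.adapting = True

    # -- likelihood deltas ------------------------------------------------
    def _eta_shift_delta(self, d_eta: np.ndarray) -> tuple[float, np.ndarray]:
        eta_new = self.eta + d_eta
        le_new = np.log(self.k + np.exp(eta_new))
        delta = np.dot(self.y, d_eta) - np.dot(self.y + self.k, le_new - self.le)
        return float(delta), le_new

    def _norm_prior_delta(self, new: float, old: float) -> float:
        s2 = self.spec.prior_sd_coefficients**2
        return (old * old - new * new) / (2 * s2)

    # -- scalar RW updates -------------------------------------------------
    def update_b0(self):
        d = self.rng.normal(0, self.s_b0)
        eta_new = self.eta + d
        le_new = np.log(self.k + np.exp(eta_new))
        delta = self.sum_y * d - np.dot(self.y + self.k, le_new - self.le)
        delta += self._norm_prior_delta(self.b0 + d, self.b0)
        if np.log(self.rng.uniform()) < delta:
            self.b0 += d
            self.eta = eta_new
            self.le = le_new
            self._acc["b0"] += 1

    def update_gamma(self):
        for j in range(len(self.gamma)):
            dg = self.rng.normal(0, self.s_gamma[j])
            zj = self.d.Z[:, j]
            eta_new = self.eta + dg * zj
            le_new = np.log(self.k + np.exp(eta_new))
            delta = self.yZ[j] * dg - np.dot(self.y + self.k, le_new - self.le)
            delta += self._norm_prior_delta(self.gamma[j] + dg, self.gamma[j])
            if np.log(self.rng.uniform()) < delta:
                self.gamma[j] += dg
                self.eta = eta_new
                self.le = le_new
                self._acc_gamma[j] += 1

    def update_k(self):
        lk_new = np.log(self.k) + self.rng.normal(0, self.s_k)
        k_new = float(np.exp(lk_new))
        ll_old = _data_loglik(self.y, self.eta, self.k)
        ll_new = _data_loglik(self.y, self.eta, k_new)
        a, r = self.spec.prior_k_shape, self.spec.prior_k_rate
        # Gamma(a, rate r) prior on k plus log-scale Jacobian
        prior = (a - 1) * (lk_new - np.log(self.k)) - r * (k_new - self.k)
        jac = lk_new - np.log(self.k)
        if np.log(self.rng.uniform()) < ll_new - ll_old + prior + jac:
            self.k = k_new
            self.le = np.log(self.k + np.exp(self.eta))
            self._acc["k"] += 1

    # -- site effects, vectorized -----------------------------------------
    def update_a(self):
        d = self.d
        eps = self.rng.normal(0, self.s_a)
        d_eta = eps[d.site_idx]
        eta_new = self.eta + d_eta
        le_new = np.log(self.k + np.exp(eta_new))
        per_obs = self.y * d_eta - (self.y + self.k) * (le_new - self.le)
        site_delta = np.bincount(d.site_idx, weights=per_obs, minlength=d.n_sites)
        R_s = self.R[d.site_eco]
        tau2 = max(self.tau, 1e-8) ** 2
        prior = ((self.a - R_s) ** 2 - (self.a + eps - R_s) ** 2) / (2 * tau2)
        accept = np.log(self.rng.uniform(size=d.n_sites)) < site_delta + prior
        if accept.any():
            self.a = np.where(accept, self.a + eps, self.a)
            obs_acc = accept[d.site_idx]
            self.eta = np.where(obs_acc, eta_new, self.eta)
            self.le = np.where(obs_acc, le_new, self.le)
        self._acc_a += accept

    # -- conjugate Gibbs ---------------------------------------------------
    def update_R(self):
        d = self.d
        tau2 = max(self.tau, 1e-8) ** 2
        T2 = max(self.T, 1e-8) ** 2
        g = self.mu + self.b_div * d.d_z
        sums = np.bincount(d.site_eco, weights=self.a, minlength=d.n_eco)
        prec = self.site_counts / tau2 + 1.0 / T2
        mean = (sums / tau2 + g / T2) / prec
        self.R = mean + self.rng.standard_normal(d.n_eco) / np.sqrt(prec)

    def update_mu_bdiv(self):
        d = self.d
        T2 = max(self.T, 1e-8) ** 2
        X = np.column_stack([np.ones(d.n_eco), d.d_z])
        s2 = self.spec.prior_sd_coefficients**2
        A = X.T @ X / T2 + np.eye(2) / s2
        b = X.T @ self.R / T2
        L = np.linalg.cholesky(A)
        mean = np.linalg.solve(A, b)
        z = self.rng.standard_normal(2)
        draw = mean + np.linalg.solve(L.T, z)
        self.mu, self.b_div = float(draw[0]), float(draw[1])

    # -- variance components (log-scale RW) --------------------------------
    def _sd_logpost(self, sd: float, resid_sq_sum: float, m: int) -> float:
        if sd <= 0:
            return -np.inf
        return (
            -m * np.log(sd)
            - resid_sq_sum / (2 * sd * sd)
            + _half_cauchy_logpdf(sd, self.spec.prior_sd_scale)
            + np.log(sd)  # Jacobian of the log parameterization
        )

    def update_tau(self):
        resid = self.a - self.R[self.d.site_eco]
        ssq = float(np.dot(resid, resid))
        new = float(self.tau * np.exp(self.rng.normal(0, self.s_tau)))
        delta = self._sd_logpost(new, ssq, self.d.n_sites) - self._sd_logpost(
            self.tau, ssq, self.d.n_sites
        )
        if np.log(self.rng.uniform()) < delta:
            self.tau = new
            self._acc["tau"] += 1

    def update_T(self):
        g = self.mu + self.b_div * self.d.d_z
        resid = self.R - g
        ssq = float(np.dot(resid, resid))
        new = float(self.T * np.exp(self.rng.normal(0, self.s_T)))
        delta = self._sd_logpost(new, ssq, self.d.n_eco) - self._sd_logpost(
            self.T, ssq, self.d.n_eco
        )
        if np.log(self.rng.uniform()) < delta:
            self.T = new
            self._acc["T"] += 1

    def recenter(self):
        # exact Gibbs move along (b0+c, a-c, R-c, mu-c); likelihood-invariant
        s2 = self.spec.prior_sd_coefficients**2
        prec = 2.0 / s2
        mean = (self.mu - self.b0) / 2.0
        c = float(mean + self.rng.standard_normal() / np.sqrt(prec))
        self.b0 += c
        self.mu -= c
        self.R -= c
        self.a -= c

    # -- adaptation ---------------------------------------------------------
    def maybe_adapt(self, it: int):
        if not self.adapting or (it + 1) % _ADAPT_BATCH != 0:
            return
        self._batch += 1
        step = min(0.25, 1.0 / np.sqrt(self._batch))

        def tune(scale, acc_count):
            rate = acc_count / _ADAPT_BATCH
            return scale * np.exp(step * (rate - _TARGET_ACC) / _TARGET_ACC)

        self.s_b0 = tune(self.s_b0, self._acc["b0"])
        self.s_k = tune(self.s_k, self._acc["k"])
        self.s_tau = tune(self.s_tau, self._acc["tau"])
        self.s_T = tune(self.s_T, self._acc["T"])
        self.s_gamma = self.s_gamma * np.exp(
            step * (self._acc_gamma / _ADAPT_BATCH - _TARGET_ACC) / _TARGET_ACC
        )
        self.s_a = self.s_a * np.exp(
            step * (self._acc_a / _ADAPT_BATCH - _TARGET_ACC) / _TARGET_ACC
        )
        self._acc = {key: 0 for key in self._acc}
        self._acc_gamma[:] = 0
        self._acc_a[:] = 0

    def step(self, it: int):
        self.update_b0()
        self.update_gamma()
        self.update_k()
        self.update_a()
        self.update_R()
        self.update_mu_bdiv()
        self.update_tau()
        self.update_T()
        self.recenter()
        self.maybe_adapt(it)


def sample_posterior(data: ModelData, spec: ModelSpec) -> dict[str, np.ndarray]:
    """Run the sampler; returns draw arrays keyed by parameter.

    Shapes: scalars (chains, draws); gamma (chains, draws, J);
    a (chains, draws, S); R (chains, draws, E). Burn-in is discarded and
    ``spec.thin`` applied. Fully reproducible from ``spec.seed``.
    """
    n_keep = spec.n_iterations // spec.thin
    J = data.Z.shape[1]
    out = {
        "b0": np.empty((spec.n_chains, n_keep)),
        "gamma": np.empty((spec.n_chains, n_keep, J)),
        "k": np.empty((spec.n_chains, n_keep)),
        "mu": np.empty((spec.n_chains, n_keep)),
        "b_div": np.empty((spec.n_chains, n_keep)),
        "tau": np.empty((spec.n_chains, n_keep)),
        "T": np.empty((spec.n_chains, n_keep)),
        "a": np.empty((spec.n_chains, n_keep, data.n_sites)),
        "R": np.empty((spec.n_chains, n_keep, data.n_eco)),
    }
    seeds = np.random.SeedSequence(spec.seed).spawn(spec.n_chains)
    for c in range(spec.n_chains):
        rng = np.random.default_rng(seeds[c])
        chain = _Chain(data, spec, rng)
        for it in range(spec.n_burnin):
            chain.step(it)
        chain.adapting = False
        kept = 0
        for it in range(spec.n_iterations):
            chain.step(spec.n_burnin + it)
            if (it + 1) % spec.thin == 0:
                out["b0"][c, kept] = chain.b0
                out["gamma"][c, kept] = chain.gamma
                out["k"][c, kept] = chain.k
                out["mu"][c, kept] = chain.mu
                out["b_div"][c, kept] = chain.b_div
                out["tau"][c, kept] = chain.tau
                out["T"][c, kept] = chain.T
                out["a"][c, kept] = chain.a
                out["R"][c, kept] = chain.R
                kept += 1
    return out
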