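"""Bayesian estimation of the transition model by Metropolis-within-Gibbs.

Every scalar parameter is its own Metropolis block: baseline rates lambda and
person speeds theta get Gaussian random walks on the log scale (Jacobian
included), covariate effects beta and key-action effects gamma get plain
Gaussian random walks.  During burn-in only, each block's proposal scale is
rescaled every ``adapt_interval`` iterations (x1.5 if its windowed acceptance
exceeds ``accept_high``, x0.67 if below ``accept_low``); proposals are frozen
after burn-in so the chain targets the exact posterior.

The likelihood factorizes over (counts, exposures), so each block update
touches only cached aggregates:

  * a lambda[m,l,g] update needs the group's m->l count and the
    covariate/speed-weighted exposure of state m in group g;
  * a theta_i update needs respondent i's transition count and total outgoing
    hazard mass;
  * beta and gamma updates need one O(N) reduction each.

Priors: Normal(0, sigma^2) on beta and gamma, Gamma(shape, scale) on lambda
and theta.  The Gamma(1,1) prior on theta softly resolves the lambda*theta
scale confounding (the likelihood is invariant to lambda*c, theta/c).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .log_io import LogDataset
from .msm_core import ParameterSet, compute_sufficient_statistics

__all__ = [
    "PriorSpec",
    "MCMCConfig",
    "PosteriorSamples",
    "log_prior",
    "fit",
    "gelman_rubin",
    "hpd_interval",
    "significance",
    "sensitivity_sweep",
]


@dataclass(frozen=True)
class PriorSpec:
    """Hyperparameters of the independent priors.

    Defaults: sigma_beta = sigma_gamma = 2 (inference is stable for sd >= 2),
    Gamma(1, 1) on each lambda and theta (prior mean 1, matching the
    centering of the person-speed distribution).
    """

    sigma_beta: float = 2.0
    sigma_gamma: float = 2.0
    lam_shape: float = 1.0
    lam_scale: float = 1.0
    theta_shape: float = 1.0
    theta_scale: float = 1.0

    def __post_init__(self) -> None:
        for name in ("sigma_beta", "sigma_gamma", "lam_shape", "lam_scale",
                     "theta_shape", "theta_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler run configuration.

    The default is scaled for desk use; ``large_scale()`` returns the
    large-scale preset (300,000 iterations, 100,000 burn-in, thin 10,
    5 chains) used for full-size analyses.
    """

    n_iter: int = 20_000
    burn_in: int = 5_000
    thin: int = 5
    n_chains: int = 5
    seed: int = 0
    accept_low: float = 0.2
    accept_high: float = 0.5
    adapt_interval: int = 100

    def __post_init__(self) -> None:
        if not (0 < self.burn_in < self.n_iter):
            raise ValueError("require 0 < burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if not (0 < self.accept_low < self.accept_high < 1):
            raise ValueError("require 0 < accept_low < accept_high < 1")
        if self.adapt_interval < 1:
            raise ValueError("adapt_interval must be >= 1")

    @staticmethod
    def large_scale(seed: int = 0) -> "MCMCConfig":
        return MCMCConfig(n_iter=300_000, burn_in=100_000, thin=10,
                          n_chains=5, seed=seed)


@dataclass
class PosteriorSamples:
    """Thinned post-burn-in draws from all chains plus bookkeeping.

    ``draws`` has shape (n_chains, n_draws, n_params); ``names`` labels the
    parameter axis.  ``acceptance_rates`` holds per-chain, per-block
    acceptance fractions measured over post-burn-in iterations only.
    """

    draws: np.ndarray
    names: list[str]
    acceptance_rates: np.ndarray
    config: MCMCConfig
    priors: PriorSpec
    states: list[str]
    key_set: frozenset[str]
    support: dict[int, frozenset[tuple[str, str]]]
    respondent_ids: list[str]
    covariate_names: list[str]
    groups: list[int]
    index: dict[str, object] = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_draws(self) -> int:
        return self.draws.shape[1]

    def flat(self, name: str) -> np.ndarray:
        """All chains' draws of one named parameter, concatenated."""
        j = self.names.index(name)
        return self.draws[:, :, j].reshape(-1)

    def to_frame(self) -> pd.DataFrame:
        """Long-format draws: columns chain, draw, parameter, value."""
        c, d, p = self.draws.shape
        return pd.DataFrame({
            "chain": np.repeat(np.arange(c), d * p),
            "draw": np.tile(np.repeat(np.arange(d), p), c),
            "parameter": np.tile(self.names, c * d),
            "value": self.draws.reshape(-1),
        })

    def mean_parameter_set(self, renormalize: bool = False) -> ParameterSet:
        """Posterior-mean plug-in ParameterSet.

        With ``renormalize=True`` each stored draw is first rescaled so the
        geometric mean of the thetas is 1 (lambdas absorb the factor),
        removing the soft scale confounding from the report.
        """
        draws = self.draws.reshape(-1, len(self.names)).copy()
        th_sl: slice | None = self.index.get("theta")
        if renormalize and th_sl is not None and th_sl.stop > th_sl.start:
            log_gm = np.log(draws[:, th_sl]).mean(axis=1, keepdims=True)
            scale = np.exp(log_gm)
            draws[:, th_sl] /= scale
            for g in self.groups:
                draws[:, self.index[("lam", g)]] *= scale
        mean = draws.mean(axis=0)
        lam = {}
        for g in self.groups:
            sl = self.index[("lam", g)]
            for (m, l), v in zip(self.index[("lam_pairs", g)], mean[sl]):
                lam[(m, l, g)] = float(v)
        theta = {rid: 1.0 for rid in self.respondent_ids}
        if th_sl is not None:
            for rid, v in zip(self.respondent_ids, mean[th_sl]):
                theta[rid] = float(v)
        beta_sl = self.index.get("beta")
        beta = mean[beta_sl] if beta_sl is not None else np.empty(0)
        gamma1 = {g: 0.0 for g in self.groups}
        gamma2 = {g: 0.0 for g in self.groups}
        for g in self.groups:
            if ("gamma1", g) in self.index:
                gamma1[g] = float(mean[self.index[("gamma1", g)]])
                gamma2[g] = float(mean[self.index[("gamma2", g)]])
        support = {g: self.support[g] for g in self.groups}
        # a missing group keeps an empty support so downstream code can ask
        for g in (0, 1):
            support.setdefault(g, frozenset())
            gamma1.setdefault(g, 0.0)
            gamma2.setdefault(g, 0.0)
        return ParameterSet(support=support, lam=lam, theta=theta,
                            beta=np.asarray(beta, dtype=float),
                            gamma1=gamma1, gamma2=gamma2,
                            key_set=self.key_set, states=list(self.states))

    def summary(self, level: float = 0.95) -> pd.DataFrame:
        """Posterior mean, sd, HPD bounds, R-hat and significance per parameter."""
        flat = self.draws.reshape(-1, len(self.names))
        rows = []
        rhat = gelman_rubin(self) if self.n_chains >= 2 else {}
        for j, name in enumerate(self.names):
            lo, hi = hpd_interval(flat[:, j], level)
            rows.append({
                "parameter": name,
                "mean": flat[:, j].mean(),
                "sd": flat[:, j].std(ddof=1),
                "hpd_lo": lo,
                "hpd_hi": hi,
                "rhat": rhat.get(name, np.nan),
                "significant": not (lo <= 0.0 <= hi),
            })
        return pd.DataFrame(rows)


def log_prior(params: ParameterSet, priors: PriorSpec) -> float:
    """Sum of independent log prior densities for a full parameter set."""
    lp = 0.0
    for v in params.lam.values():
        if v <= 0:
            return -math.inf
        lp += sps.gamma.logpdf(v, priors.lam_shape, scale=priors.lam_scale)
    for v in params.theta.values():
        if v <= 0:
            return -math.inf
        lp += sps.gamma.logpdf(v, priors.theta_shape, scale=priors.theta_scale)
    lp += sps.norm.logpdf(params.beta, 0.0, priors.sigma_beta).sum()
    for g in params.gamma1:
        lp += sps.norm.logpdf(params.gamma1[g], 0.0, priors.sigma_gamma)
        lp += sps.norm.logpdf(params.gamma2[g], 0.0, priors.sigma_gamma)
    return float(lp)


# ---------------------------------------------------------------------------
# internal data layout


class _ModelData:
    """Aggregated arrays the sampler actually touches."""

    def __init__(self, dataset: LogDataset, key_set, support_policy: str,
                 sample_theta: bool):
        stats, support = compute_sufficient_statistics(dataset, support_policy)
        self.stats = stats
        self.states = list(dataset.vocabulary)
        sidx = {s: i for i, s in enumerate(self.states)}
        self.E = len(self.states)
        self.N = dataset.n_respondents
        self.p = dataset.n_covariates
        self.key_set = frozenset(key_set)
        self.kvec = np.array([s in self.key_set for s in self.states])
        self.sample_theta = sample_theta

        self.rids = [r.id for r in dataset.records]
        self.grp = dataset.groups()
        self.groups = sorted(set(self.grp.tolist()))
        self.X = dataset.covariate_matrix().reshape(self.N, self.p)
        self.support = {g: support[g] for g in self.groups}

        self.Emat = np.zeros((self.N, self.E))
        self.n_i = np.zeros(self.N)
        for i, rec in enumerate(dataset.records):
            for m, e in stats.exposure[rec.id].items():
                self.Emat[i, sidx[m]] = e
            self.n_i[i] = stats.n_transitions(rec.id)
        self.Sx = self.X.T @ self.n_i  # sum_i n_i x_ik

        self.members = {g: np.where(self.grp == g)[0] for g in self.groups}
        self.rows: dict[int, np.ndarray] = {}
        self.cols: dict[int, np.ndarray] = {}
        self.D: dict[int, np.ndarray] = {}
        self.pairs: dict[int, list[tuple[str, str]]] = {}
        self.C1: dict[int, float] = {}
        self.C2: dict[int, float] = {}
        for g in self.groups:
            pairs = sorted(self.support[g])
            if not pairs:
                raise ValueError(f"empty support for group {g}")
            self.pairs[g] = pairs
            self.rows[g] = np.array([sidx[m] for m, _ in pairs])
            self.cols[g] = np.array([sidx[l] for _, l in pairs])
            dmat = np.zeros(len(pairs))
            pair_pos = {pr: k for k, pr in enumerate(pairs)}
            c1 = c2 = 0.0
            for i in self.members[g]:
                for pr, d in stats.counts[self.rids[i]].items():
                    if pr not in pair_pos:
                        raise ValueError(
                            f"observed transition {pr} outside support of group {g}")
                    dmat[pair_pos[pr]] += d
                    if pr[0] in self.key_set:
                        c1 += d
                    if pr[1] in self.key_set:
                        c2 += d
            self.D[g] = dmat
            self.C1[g] = c1
            self.C2[g] = c2
        # group-level exposure per state (for initialization)
        self.Egrp = {g: self.Emat[self.members[g]].sum(axis=0)
                     for g in self.groups}


def _run_chain(data: _ModelData, priors: PriorSpec, config: MCMCConfig,
               seed: int):
    """One adaptive Metropolis-within-Gibbs chain. Returns draws + acceptance."""
    rng = np.random.default_rng(seed)
    gs = data.groups
    E, N, p = data.E, data.N, data.p
    kvec = data.kvec
    has_gamma = bool(data.key_set)

    # state
    lam = {g: np.maximum(data.D[g] / np.maximum(data.Egrp[g][data.rows[g]], 1e-12),
                         1e-3) for g in gs}
    theta = np.ones(N)
    beta = np.zeros(p)
    g1 = {g: 0.0 for g in gs}
    g2 = {g: 0.0 for g in gs}

    # proposal sds and acceptance bookkeeping, one entry per scalar block
    sd_lam = {g: np.full(len(data.pairs[g]), 0.5) for g in gs}
    sd_theta = np.full(N, 0.5)
    sd_beta = np.full(p, 0.2)
    sd_g1 = {g: 0.3 for g in gs}
    sd_g2 = {g: 0.3 for g in gs}
    win_lam = {g: np.zeros(len(data.pairs[g])) for g in gs}
    win_theta = np.zeros(N)
    win_beta = np.zeros(p)
    win_g1 = {g: 0.0 for g in gs}
    win_g2 = {g: 0.0 for g in gs}
    post_lam = {g: np.zeros(len(data.pairs[g])) for g in gs}
    post_theta = np.zeros(N)
    post_beta = np.zeros(p)
    post_g1 = {g: 0.0 for g in gs}
    post_g2 = {g: 0.0 for g in gs}

    a_l, s_l = priors.lam_shape, priors.lam_scale
    a_t, s_t = priors.theta_shape, priors.theta_scale
    inv_sl, inv_st = 1.0 / s_l, 1.0 / s_t
    sb2 = priors.sigma_beta ** 2
    sg2 = priors.sigma_gamma ** 2

    km = {g: kvec[data.rows[g]] for g in gs}
    kl = {g: kvec[data.cols[g]] for g in gs}

    n_keep = (config.n_iter - config.burn_in) // config.thin
    n_par = (sum(len(data.pairs[g]) for g in gs)
             + (N if data.sample_theta else 0) + p
             + (4 if has_gamma and len(gs) == 2 else (2 if has_gamma else 0)))
    draws = np.empty((n_keep, n_par))
    keep = 0

    eta = data.X @ beta if p else np.zeros(N)

    for it in range(config.n_iter):
        in_burn = it < config.burn_in
        c = theta * np.exp(eta)

        # ---- lambda blocks (conditionally independent; vectorized) ----
        for g in gs:
            mem = data.members[g]
            Wg = data.Emat[mem].T @ c[mem]
            kap = np.exp(g1[g] * km[g] + g2[g] * kl[g]) if has_gamma else 1.0
            rate = Wg[data.rows[g]] * kap + inv_sl
            eps = rng.normal(0.0, sd_lam[g])
            lam_new = lam[g] * np.exp(eps)
            delta = (data.D[g] + a_l) * eps - rate * (lam_new - lam[g])
            acc = np.log(rng.random(len(eps))) < delta
            lam[g][acc] = lam_new[acc]
            if in_burn:
                win_lam[g][acc] += 1
            else:
                post_lam[g][acc] += 1

        # outgoing-hazard caches after the lambda update
        ug = {}
        for g in gs:
            lamk = lam[g] * (np.exp(g2[g] * kl[g]) if has_gamma else 1.0)
            Lam = np.bincount(data.rows[g], weights=lamk, minlength=E)
            ug[g] = (np.exp(g1[g] * kvec) if has_gamma else 1.0) * Lam
        qraw = np.empty(N)
        for g in gs:
            mem = data.members[g]
            qraw[mem] = data.Emat[mem] @ ug[g]

        # ---- theta blocks (vectorized) ----
        if data.sample_theta:
            q = np.exp(eta) * qraw
            eps = rng.normal(0.0, sd_theta)
            theta_new = theta * np.exp(eps)
            delta = (data.n_i + a_t) * eps - (q + inv_st) * (theta_new - theta)
            acc = np.log(rng.random(N)) < delta
            theta[acc] = theta_new[acc]
            if in_burn:
                win_theta[acc] += 1
            else:
                post_theta[acc] += 1

        # ---- beta blocks (sequential scalar updates) ----
        if p:
            expeta = np.exp(eta)
            for k in range(p):
                bn = beta[k] + rng.normal(0.0, sd_beta[k])
                eta_new = eta + (bn - beta[k]) * data.X[:, k]
                delta = ((bn - beta[k]) * data.Sx[k]
                         - float(theta @ (qraw * (np.exp(eta_new) - expeta)))
                         - (bn * bn - beta[k] * beta[k]) / (2.0 * sb2))
                if math.log(rng.random()) < delta:
                    beta[k] = bn
                    eta = eta_new
                    expeta = np.exp(eta)
                    if in_burn:
                        win_beta[k] += 1
                    else:
                        post_beta[k] += 1
        else:
            expeta = np.exp(eta)

        # ---- gamma blocks ----
        if has_gamma:
            w_i = theta * expeta
            for g in gs:
                mem = data.members[g]
                lamk = lam[g] * np.exp(g2[g] * kl[g])
                Lam = np.bincount(data.rows[g], weights=lamk, minlength=E)
                # gamma1: scales hazards out of key source states
                t1 = float(w_i[mem] @ (data.Emat[mem][:, kvec] @ Lam[kvec]))
                gn = g1[g] + rng.normal(0.0, sd_g1[g])
                delta = (data.C1[g] * (gn - g1[g])
                         - (math.exp(gn) - math.exp(g1[g])) * t1
                         - (gn * gn - g1[g] * g1[g]) / (2.0 * sg2))
                if math.log(rng.random()) < delta:
                    g1[g] = gn
                    if in_burn:
                        win_g1[g] += 1
                    else:
                        post_g1[g] += 1
                # gamma2: scales hazards into key destination states
                B = np.bincount(data.rows[g][kl[g]], weights=lam[g][kl[g]],
                                minlength=E)
                t2 = float(w_i[mem] @ (data.Emat[mem]
                                       @ (np.exp(g1[g] * kvec) * B)))
                gn = g2[g] + rng.normal(0.0, sd_g2[g])
                delta = (data.C2[g] * (gn - g2[g])
                         - (math.exp(gn) - math.exp(g2[g])) * t2
                         - (gn * gn - g2[g] * g2[g]) / (2.0 * sg2))
                if math.log(rng.random()) < delta:
                    g2[g] = gn
                    if in_burn:
                        win_g2[g] += 1
                    else:
                        post_g2[g] += 1

        # ---- burn-in-only proposal adaptation ----
        if in_burn and (it + 1) % config.adapt_interval == 0:
            inv_w = 1.0 / config.adapt_interval
            for g in gs:
                r = win_lam[g] * inv_w
                sd_lam[g][r > config.accept_high] *= 1.5
                sd_lam[g][r < config.accept_low] *= 0.67
                win_lam[g][:] = 0.0
                r = win_g1[g] * inv_w
                if r > config.accept_high:
                    sd_g1[g] *= 1.5
                elif r < config.accept_low:
                    sd_g1[g] *= 0.67
                win_g1[g] = 0.0
                r = win_g2[g] * inv_w
                if r > config.accept_high:
                    sd_g2[g] *= 1.5
                elif r < config.accept_low:
                    sd_g2[g] *= 0.67
                win_g2[g] = 0.0
            if data.sample_theta:
                r = win_theta * inv_w
                sd_theta[r > config.accept_high] *= 1.5
                sd_theta[r < config.accept_low] *= 0.67
                win_theta[:] = 0.0
            if p:
                r = win_beta * inv_w
                sd_beta[r > config.accept_high] *= 1.5
                sd_beta[r < config.accept_low] *= 0.67
                win_beta[:] = 0.0

        # ---- storage ----
        if not in_burn and (it - config.burn_in + 1) % config.thin == 0:
            vec = [lam[g] for g in gs]
            if data.sample_theta:
                vec.append(theta)
            if p:
                vec.append(beta)
            if has_gamma:
                vec.append(np.array([g1[g] for g in gs]))
                vec.append(np.array([g2[g] for g in gs]))
            draws[keep] = np.concatenate([np.atleast_1d(v) for v in vec])
            keep += 1

    n_post = config.n_iter - config.burn_in
    acc_vec = [post_lam[g] / n_post for g in gs]
    if data.sample_theta:
        acc_vec.append(post_theta / n_post)
    if p:
        acc_vec.append(post_beta / n_post)
    if has_gamma:
        acc_vec.append(np.array([post_g1[g] for g in gs]) / n_post)
        acc_vec.append(np.array([post_g2[g] for g in gs]) / n_post)
    acceptance = np.concatenate([np.atleast_1d(a) for a in acc_vec])
    return draws[:keep], acceptance


def fit(dataset: LogDataset, key_set, priors: PriorSpec | None = None,
        config: MCMCConfig | None = None, support_policy: str = "observed",
        sample_theta: bool = True) -> PosteriorSamples:
    """Fit the transition model to a dataset.

    ``key_set`` is the collection of key actions entering the gamma effects
    (empty set drops the gamma parameters).  Chains are seeded independently
    as ``config.seed + chain``; two runs with the same config are identical.
    ``sample_theta=False`` pins every person speed at 1 (useful for
    conjugate checks and very sparse data).

    If only one correctness group is present, the absent group's parameters
    are dropped rather than sampled from the prior.
    """
    priors = priors or PriorSpec()
    config = config or MCMCConfig()
    data = _ModelData(dataset, key_set, support_policy, sample_theta)

    beta_names = [f"beta[{name}]" for name in dataset.covariate_names]
    names: list[str] = []
    index: dict[str, object] = {}
    pos = 0
    for g in data.groups:
        n = len(data.pairs[g])
        index[("lam", g)] = slice(pos, pos + n)
        index[("lam_pairs", g)] = data.pairs[g]
        names += [f"lam[{m}->{l},g={g}]" for m, l in data.pairs[g]]
        pos += n
    if sample_theta:
        index["theta"] = slice(pos, pos + data.N)
        names += [f"theta[{rid}]" for rid in data.rids]
        pos += data.N
    if data.p:
        index["beta"] = slice(pos, pos + data.p)
        names += beta_names
        pos += data.p
    if data.key_set:
        for g in data.groups:
            index[("gamma1", g)] = pos
            names.append(f"gamma1[g={g}]")
            pos += 1
        for g in data.groups:
            index[("gamma2", g)] = pos
            names.append(f"gamma2[g={g}]")
            pos += 1

    all_draws = []
    all_acc = []
    for chain in range(config.n_chains):
        d, a = _run_chain(data, priors, config, config.seed + chain)
        all_draws.append(d)
        all_acc.append(a)
    draws = np.stack(all_draws)
    acceptance = np.stack(all_acc)
    if not np.all(np.isfinite(draws)):
        raise RuntimeError("non-finite draws encountered")

    return PosteriorSamples(
        draws=draws, names=names, acceptance_rates=acceptance, config=config,
        priors=priors, states=data.states, key_set=data.key_set,
        support=data.support, respondent_ids=list(data.rids),
        covariate_names=list(dataset.covariate_names),
        groups=list(data.groups), index=index)


def gelman_rubin(samples: PosteriorSamples | np.ndarray,
                 names: list[str] | None = None) -> dict[str, float]:
    """Classic Gelman-Rubin R-hat per scalar parameter.

    R-hat = sqrt( ((n-1)/n * W + B/n) / W ) with W the mean within-chain
    variance and B the between-chain variance of the chain means (times n).
    Requires >= 2 chains of >= 10 draws.
    """
    if isinstance(samples, PosteriorSamples):
        arr = samples.draws
        names = samples.names
    else:
        arr = np.asarray(samples)
        if names is None:
            names = [f"p{j}" for j in range(arr.shape[2])]
    m, n = arr.shape[0], arr.shape[1]
    if m < 2:
        raise ValueError("Gelman-Rubin requires at least two chains")
    if n < 10:
        raise ValueError("Gelman-Rubin requires at least 10 draws per chain")
    chain_means = arr.mean(axis=1)
    w = arr.var(axis=1, ddof=1).mean(axis=0)
    b = n * chain_means.var(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rhat = np.sqrt(((n - 1) / n * w + b / n) / w)
    rhat = np.where(w == 0.0, 1.0, rhat)  # degenerate constant parameter
    return {name: float(r) for name, r in zip(names, rhat)}


def hpd_interval(draws: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``ceil(level * n)`` of the draws."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    n = x.size
    if n < 20:
        raise ValueError("need at least 20 draws for an HPD interval")
    m = int(math.ceil(level * n))
    widths = x[m - 1:] - x[: n - m + 1]
    j = int(np.argmin(widths))
    return float(x[j]), float(x[j + m - 1])


def significance(draws: np.ndarray, level: float = 0.95) -> tuple[bool, int]:
    """HPD-based significance: (significant, sign).

    Significant iff the ``level`` HPD interval excludes 0; the sign is +1
    when the interval lies above 0, -1 below, 0 otherwise.
    """
    lo, hi = hpd_interval(draws, level)
    if lo > 0.0:
        return True, 1
    if hi < 0.0:
        return True, -1
    return False, 0


def sensitivity_sweep(dataset: LogDataset, key_set, config: MCMCConfig,
                      grid: list[PriorSpec],
                      monitor: list[str] | None = None,
                      support_policy: str = "observed") -> pd.DataFrame:
    """Refit under each prior in ``grid`` and tabulate posterior summaries.

    ``monitor`` restricts the output to named parameters (prefix match, e.g.
    ``"beta"``); by default beta and gamma are monitored.  Output columns:
    grid point label, parameter, mean, sd, hpd_lo, hpd_hi.
    """
    rows = []
    for j, priors in enumerate(grid):
        samples = fit(dataset, key_set, priors=priors, config=config,
                      support_policy=support_policy)
        prefixes = monitor if monitor is not None else ["beta", "gamma"]
        label = (f"sigma_beta={priors.sigma_beta},"
                 f"sigma_gamma={priors.sigma_gamma},"
                 f"lam=Gamma({priors.lam_shape},{priors.lam_scale}),"
                 f"theta=Gamma({priors.theta_shape},{priors.theta_scale})")
        flat = samples.draws.reshape(-1, len(samples.names))
        for jj, name in enumerate(samples.names):
            if not any(name.startswith(pref) for pref in prefixes):
                continue
            lo, hi = hpd_interval(flat[:, jj])
            rows.append({"grid_index": j, "prior": label, "parameter": name,
                         "mean": flat[:, jj].mean(),
                         "sd": flat[:, jj].std(ddof=1),
                         "hpd_lo": lo, "hpd_hi": hi})
    return pd.DataFrame(rows)
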