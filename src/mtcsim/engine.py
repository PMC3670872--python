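"""Bayesian random-effects mixed-treatment-comparison (MTC) model.

Implements the standard arm-based consistency model for binary outcomes:

    r_ik ~ Binomial(n_ik, p_ik)
    logit(p_ik) = mu_i + delta_ik          (delta = 0 for the baseline arm)
    delta_i ~ Normal(d_t(i,k) - d_t(i,base), Sigma_i)

with between-trial standard deviation ``sigma`` shared across comparisons;
for a trial with ``m`` non-baseline arms the random-effect vector has
variance ``sigma^2`` and pairwise covariance ``sigma^2 / 2`` (homogeneous
multi-arm correlation).  ``d`` are the basic parameters: log odds ratios of
each treatment against the network's reference (the first treatment), with
every other contrast derived by consistency, ``d_st = d_1t - d_1s``.

Priors are vague on the log-odds scale: ``mu_i ~ N(0, 15^2)``,
``d ~ N(0, 15^2)``, ``sigma ~ Uniform(0, 5)``.

Posterior sampling is Metropolis-within-Gibbs: trial baselines and random
effects take adaptive random-walk steps against the binomial likelihood
(vectorized across trials), the basic parameters are drawn exactly from
their conjugate multivariate-normal full conditional given the random
effects, and ``sigma`` takes a random-walk step.  Step sizes adapt during
burn-in toward ~35% acceptance.  Setting ``sigma_fixed=0`` selects a
common-effect variant (no random effects) used by the closed-form oracle
checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import norm

from .network import TrialNetwork, validate_network

__all__ = [
    "MTCModelSpec",
    "MCMCConfig",
    "PosteriorSamples",
    "ContrastEstimate",
    "DiagnosticsReport",
    "fit_mtc",
    "contrast_estimates",
    "single_contrast",
    "contrast_table",
    "rank_probabilities",
    "convergence_diagnostics",
]

_ADAPT_BATCH = 50


@dataclass(frozen=True)
class MTCModelSpec:
    """Prior specification of the MTC model (log-odds scale).

    ``sigma_fixed`` pins the heterogeneity SD instead of sampling it;
    ``sigma_fixed=0`` drops the random effects entirely (common-effect
    model), which is how single-study oracle comparisons are run.
    """

    baseline_prior_sd: float = 15.0
    effect_prior_sd: float = 15.0
    sigma_upper: float = 5.0
    sigma_fixed: Optional[float] = None

    def validate(self) -> None:
        if self.baseline_prior_sd <= 0 or self.effect_prior_sd <= 0:
            raise ValueError("prior spreads must be positive")
        if self.sigma_upper <= 0:
            raise ValueError("sigma_upper must be positive")
        if self.sigma_fixed is not None and self.sigma_fixed < 0:
            raise ValueError("sigma_fixed must be >= 0")


@dataclass(frozen=True)
class MCMCConfig:
    chains: int = 2
    burn_in: int = 5000
    draws: int = 10000
    thin: int = 1
    seed: Union[int, Sequence[int], None] = None

    def validate(self) -> None:
        if min(self.chains, self.burn_in, self.draws, self.thin) < 1:
            raise ValueError("chains, burn_in, draws and thin must all be >= 1")


@dataclass
class PosteriorSamples:
    """MCMC draws of the basic parameters and the heterogeneity SD.

    ``d`` has shape ``(chains, draws, k-1)``: the log-OR of each non-reference
    treatment versus ``treatments[0]``.  ``sigma`` has shape
    ``(chains, draws)`` and is constant when the model fixed it.
    """

    treatments: list[str]
    d: np.ndarray
    sigma: np.ndarray

    @property
    def n_chains(self) -> int:
        return self.d.shape[0]

    @property
    def n_draws(self) -> int:
        return self.d.shape[1]

    @property
    def k(self) -> int:
        return self.d.shape[2] + 1

    def effect_draws(self) -> np.ndarray:
        """Pooled draws of all k treatment effects, reference column = 0;
        shape ``(chains * draws, k)``."""
        pooled = self.d.reshape(-1, self.d.shape[2])
        return np.concatenate([np.zeros((pooled.shape[0], 1)), pooled], axis=1)

    def contrast_draws(self, s: str, t: str) -> np.ndarray:
        """Pooled draws of the log-OR of ``t`` relative to ``s``."""
        eff = self.effect_draws()
        return eff[:, self.treatments.index(t)] - eff[:, self.treatments.index(s)]

    def to_frame(self) -> pd.DataFrame:
        """Draws in columnar form (chain, draw, one column per parameter),
        suitable for dumping to CSV for external diagnostics."""
        chains, draws, k1 = self.d.shape
        data = {
            "chain": np.repeat(np.arange(chains), draws),
            "draw": np.tile(np.arange(draws), chains),
        }
        for i, t in enumerate(self.treatments[1:]):
            data[f"d[{t}]"] = self.d[:, :, i].reshape(-1)
        data["sigma"] = self.sigma.reshape(-1)
        return pd.DataFrame(data)


@dataclass(frozen=True)
class ContrastEstimate:
    """One pairwise contrast: log-OR of ``pair[1]`` relative to ``pair[0]``."""

    pair: tuple[str, str]
    log_or: float
    se: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    significant: bool


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------


class _Design:
    """Flat array view of a trial network for the sampler."""

    def __init__(self, net: TrialNetwork):
        trt_index = {t: i for i, t in enumerate(net.treatments)}
        arm_trial, arm_r, arm_n, arm_t = [], [], [], []
        d_trial, d_t, d_b, d_m, d_pos, nb_arm = [], [], [], [], [], []
        for i, trial in enumerate(net.trials):
            base_t = trt_index[trial.arms[0].treatment]
            m = len(trial.arms) - 1
            for j, arm in enumerate(trial.arms):
                arm_idx = len(arm_trial)
                arm_trial.append(i)
                arm_r.append(arm.r)
                arm_n.append(arm.n)
                arm_t.append(trt_index[arm.treatment])
                if j > 0:
                    d_trial.append(i)
                    d_t.append(trt_index[arm.treatment])
                    d_b.append(base_t)
                    d_m.append(m)
                    d_pos.append(j - 1)
                    nb_arm.append(arm_idx)
        self.n_trials = len(net.trials)
        self.k = len(net.treatments)
        self.arm_trial = np.asarray(arm_trial)
        self.arm_r = np.asarray(arm_r, dtype=float)
        self.arm_n = np.asarray(arm_n, dtype=float)
        self.arm_t = np.asarray(arm_t)
        self.trial_base_t = np.asarray(
            [trt_index[tr.arms[0].treatment] for tr in net.trials]
        )
        self.delta_trial = np.asarray(d_trial, dtype=np.intp)
        self.delta_t = np.asarray(d_t, dtype=np.intp)
        self.delta_b = np.asarray(d_b, dtype=np.intp)
        self.delta_m = np.asarray(d_m, dtype=float)
        self.delta_pos = np.asarray(d_pos, dtype=np.intp)
        self.nb_arm = np.asarray(nb_arm, dtype=np.intp)
        self.n_delta = len(nb_arm)
        # design matrix delta_mean = X @ d  (d indexed by treatment 1..k-1)
        X = np.zeros((self.n_delta, self.k - 1))
        for j in range(self.n_delta):
            if self.delta_t[j] > 0:
                X[j, self.delta_t[j] - 1] += 1.0
            if self.delta_b[j] > 0:
                X[j, self.delta_b[j] - 1] -= 1.0
        self.X = X
        # W0: scaled inverse of the multi-arm correlation structure,
        # Sigma_block = sigma^2/2 (I + J)  =>  Sigma^{-1} = W0 / sigma^2
        W0 = np.zeros((self.n_delta, self.n_delta))
        for i in range(self.n_trials):
            idx = np.flatnonzero(self.delta_trial == i)
            m = len(idx)
            if m:
                block = 2.0 * (np.eye(m) - np.ones((m, m)) / (m + 1))
                W0[np.ix_(idx, idx)] = block
        self.W0 = W0
        self.M1 = X.T @ W0 @ X
        # position passes: deltas sharing a within-trial position are in
        # distinct trials, hence conditionally independent
        self.pos_groups = [
            np.flatnonzero(self.delta_pos == p)
            for p in range(int(self.delta_pos.max()) + 1 if self.n_delta else 0)
        ]
        # random effects touched by each basic parameter (translation moves)
        self.tr_idx = [np.flatnonzero(X[:, t]) for t in range(self.k - 1)]
        self.tr_coef = [X[idx, t] for t, idx in enumerate(self.tr_idx)]
        # per-treatment affected arms for the common-effect d update
        self.fe_idx = []
        self.fe_coef = []
        for t in range(1, self.k):
            coef = (self.arm_t == t).astype(float) - (
                self.trial_base_t[self.arm_trial] == t
            ).astype(float)
            idx = np.flatnonzero(coef)
            self.fe_idx.append(idx)
            self.fe_coef.append(coef[idx])


def _binom_loglik(eta: np.ndarray, r: np.ndarray, n: np.ndarray) -> np.ndarray:
    return r * eta - n * np.logaddexp(0.0, eta)


def _adapt(step: np.ndarray, acc: np.ndarray, n: int) -> None:
    rate = acc / n
    np.multiply(step, np.exp(rate - 0.35), out=step)
    np.clip(step, 1e-4, 25.0, out=step)


def _init_state(design: _Design, rng: np.random.Generator):
    p_hat = (design.arm_r + 0.5) / (design.arm_n + 1.0)
    lo = np.log(p_hat / (1.0 - p_hat))
    base_mask = np.ones(len(lo), dtype=bool)
    base_mask[design.nb_arm] = False
    mu = np.zeros(design.n_trials)
    mu[design.arm_trial[base_mask]] = lo[base_mask]
    mu += 0.05 * rng.standard_normal(design.n_trials)
    delta = lo[design.nb_arm] - mu[design.delta_trial]
    d = 0.1 * rng.standard_normal(design.k - 1)
    return mu, delta, d


def _run_chain_re(
    design: _Design,
    spec: MTCModelSpec,
    mcmc: MCMCConfig,
    rng: np.random.Generator,
):
    """Random-effects chain; returns (d draws, sigma draws)."""
    T, D, K1 = design.n_trials, design.n_delta, design.k - 1
    pv_mu = spec.baseline_prior_sd**2
    pv_d = spec.effect_prior_sd**2
    sigma_sampled = spec.sigma_fixed is None
    mu, delta, d = _init_state(design, rng)
    sigma = 0.2 + 0.1 * rng.random() if sigma_sampled else float(spec.sigma_fixed)

    s_mu = np.full(T, 0.4)
    s_delta = np.full(D, 0.5)
    s_sigma = np.array([0.1])
    s_tr = np.full(K1, 0.2)
    s_resc = np.array([0.5])
    a_mu = np.zeros(T)
    a_delta = np.zeros(D)
    a_sigma = np.zeros(1)
    a_tr = np.zeros(K1)
    a_resc = np.zeros(1)

    n_keep = mcmc.draws // mcmc.thin
    out_d = np.empty((n_keep, K1))
    out_sigma = np.empty(n_keep)

    arm_trial, arm_r, arm_n = design.arm_trial, design.arm_r, design.arm_n
    nb_arm = design.nb_arm
    d_trial, d_t, d_b, d_m = design.delta_trial, design.delta_t, design.delta_b, design.delta_m
    X, W0, M1 = design.X, design.W0, design.M1
    eye_K1 = np.eye(K1)
    dfull = np.concatenate([[0.0], d])

    dc = np.zeros(len(arm_trial))
    total = mcmc.burn_in + mcmc.draws
    kept = 0
    for it in range(total):
        burn = it < mcmc.burn_in
        # --- trial baselines ---------------------------------------------
        dc[nb_arm] = delta
        eta = mu[arm_trial] + dc
        ll_tr = np.bincount(arm_trial, _binom_loglik(eta, arm_r, arm_n), minlength=T)
        mu_p = mu + s_mu * rng.standard_normal(T)
        ll_tr_p = np.bincount(
            arm_trial, _binom_loglik(mu_p[arm_trial] + dc, arm_r, arm_n), minlength=T
        )
        log_acc = ll_tr_p - ll_tr + (mu**2 - mu_p**2) / (2.0 * pv_mu)
        acc = np.log(rng.random(T)) < log_acc
        mu[acc] = mu_p[acc]
        if burn:
            a_mu += acc

        # --- random effects ----------------------------------------------
        pm = dfull[d_t] - dfull[d_b]
        cvar = sigma**2 * (d_m + 1.0) / (2.0 * d_m) if sigma > 0 else None
        for sel in design.pos_groups:
            arm = nb_arm[sel]
            tr = arm_trial[arm]
            eta_old = mu[tr] + delta[sel]
            prop = delta[sel] + s_delta[sel] * rng.standard_normal(len(sel))
            ll_old = _binom_loglik(eta_old, arm_r[arm], arm_n[arm])
            ll_new = _binom_loglik(mu[tr] + prop, arm_r[arm], arm_n[arm])
            if sigma > 0:
                resid = delta - pm
                blocksum = np.bincount(d_trial, resid, minlength=T)
                other = blocksum[d_trial[sel]] - resid[sel]
                cmean = pm[sel] + other / d_m[sel]
                cv = cvar[sel]
                log_acc = (
                    ll_new
                    - ll_old
                    - ((prop - cmean) ** 2 - (delta[sel] - cmean) ** 2) / (2.0 * cv)
                )
            else:  # degenerate: should not happen (fixed-effect path is separate)
                log_acc = np.full(len(sel), -np.inf)
            acc = np.log(rng.random(len(sel))) < log_acc
            delta[sel[acc]] = prop[acc]
            if burn:
                a_delta[sel] += acc

        # --- basic parameters: conjugate Gibbs draw ----------------------
        if sigma > 0:
            u = W0 @ delta
            A = M1 / sigma**2 + eye_K1 / pv_d
            b = (X.T @ u) / sigma**2
            L = np.linalg.cholesky(A)
            mean = np.linalg.solve(A, b)
            d = mean + np.linalg.solve(L.T, rng.standard_normal(K1))
            dfull = np.concatenate([[0.0], d])

        # --- translation interweave: move d_t with its random effects ----
        # residuals delta - Xd stay fixed, so the binomial likelihood of the
        # affected arms drives d directly; cures the slow centered-
        # parameterization mixing when sigma is small
        for t in range(K1):
            idx = design.tr_idx[t]
            if len(idx) == 0:
                continue
            coef = design.tr_coef[t]
            step = s_tr[t] * rng.standard_normal()
            arm = nb_arm[idx]
            eta_old = mu[arm_trial[arm]] + delta[idx]
            eta_new = eta_old + coef * step
            dll = np.sum(
                _binom_loglik(eta_new, arm_r[arm], arm_n[arm])
                - _binom_loglik(eta_old, arm_r[arm], arm_n[arm])
            )
            dll += (d[t] ** 2 - (d[t] + step) ** 2) / (2.0 * pv_d)
            if np.log(rng.random()) < dll:
                d[t] += step
                delta[idx] += coef * step
                if burn:
                    a_tr[t] += 1
        dfull = np.concatenate([[0.0], d])

        # --- heterogeneity SD --------------------------------------------
        if sigma_sampled:
            pm = dfull[d_t] - dfull[d_b]
            resid = delta - pm
            Q = resid @ (W0 @ resid)
            prop = sigma + s_sigma[0] * rng.standard_normal()
            if 0.0 < prop <= spec.sigma_upper:
                log_acc = (
                    -D * (np.log(prop) - np.log(sigma))
                    - Q / 2.0 * (1.0 / prop**2 - 1.0 / sigma**2)
                )
                if np.log(rng.random()) < log_acc:
                    sigma = prop
                    if burn:
                        a_sigma[0] += 1

            # rescale interweave: sigma and the residuals move together so
            # the scale can jump even though sigma | residuals is tight
            u = s_resc[0] * rng.standard_normal()
            prop = sigma * np.exp(u)
            if 0.0 < prop <= spec.sigma_upper:
                resid = delta - pm
                delta_new = pm + np.exp(u) * resid
                eta_old = mu[arm_trial[nb_arm]] + delta
                eta_new = mu[arm_trial[nb_arm]] + delta_new
                dll = (
                    np.sum(
                        _binom_loglik(eta_new, arm_r[nb_arm], arm_n[nb_arm])
                        - _binom_loglik(eta_old, arm_r[nb_arm], arm_n[nb_arm])
                    )
                    + u
                )
                if np.log(rng.random()) < dll:
                    sigma = prop
                    delta = delta_new
                    if burn:
                        a_resc[0] += 1

        if burn and (it + 1) % _ADAPT_BATCH == 0:
            _adapt(s_mu, a_mu, _ADAPT_BATCH)
            _adapt(s_delta, a_delta, _ADAPT_BATCH)
            _adapt(s_sigma, a_sigma, _ADAPT_BATCH)
            _adapt(s_tr, a_tr, _ADAPT_BATCH)
            _adapt(s_resc, a_resc, _ADAPT_BATCH)
            a_mu[:] = 0
            a_delta[:] = 0
            a_sigma[:] = 0
            a_tr[:] = 0
            a_resc[:] = 0
        if not burn and (it - mcmc.burn_in) % mcmc.thin == 0 and kept < n_keep:
            out_d[kept] = d
            out_sigma[kept] = sigma
            kept += 1
    return out_d[:kept], out_sigma[:kept]


def _run_chain_fe(
    design: _Design,
    spec: MTCModelSpec,
    mcmc: MCMCConfig,
    rng: np.random.Generator,
):
    """Common-effect chain (sigma fixed at 0): logit p = mu_i + d_t - d_base."""
    T, K1 = design.n_trials, design.k - 1
    pv_mu = spec.baseline_prior_sd**2
    pv_d = spec.effect_prior_sd**2
    mu, _, d = _init_state(design, rng)
    s_mu = np.full(T, 0.4)
    s_d = np.full(K1, 0.3)
    a_mu = np.zeros(T)
    a_d = np.zeros(K1)
    arm_trial, arm_r, arm_n = design.arm_trial, design.arm_r, design.arm_n
    dfull = np.concatenate([[0.0], d])
    offset = dfull[design.arm_t] - dfull[design.trial_base_t[arm_trial]]

    n_keep = mcmc.draws // mcmc.thin
    out_d = np.empty((n_keep, K1))
    kept = 0
    total = mcmc.burn_in + mcmc.draws
    for it in range(total):
        burn = it < mcmc.burn_in
        eta = mu[arm_trial] + offset
        ll_tr = np.bincount(arm_trial, _binom_loglik(eta, arm_r, arm_n), minlength=T)
        mu_p = mu + s_mu * rng.standard_normal(T)
        ll_tr_p = np.bincount(
            arm_trial, _binom_loglik(mu_p[arm_trial] + offset, arm_r, arm_n), minlength=T
        )
        acc = np.log(rng.random(T)) < ll_tr_p - ll_tr + (mu**2 - mu_p**2) / (2 * pv_mu)
        mu[acc] = mu_p[acc]
        if burn:
            a_mu += acc

        for t in range(K1):
            idx, coef = design.fe_idx[t], design.fe_coef[t]
            if len(idx) == 0:
                continue
            step = s_d[t] * rng.standard_normal()
            eta_old = mu[arm_trial[idx]] + offset[idx]
            eta_new = eta_old + coef * step
            dl = np.sum(
                _binom_loglik(eta_new, arm_r[idx], arm_n[idx])
                - _binom_loglik(eta_old, arm_r[idx], arm_n[idx])
            )
            d_new = d[t] + step
            dl += (d[t] ** 2 - d_new**2) / (2 * pv_d)
            if np.log(rng.random()) < dl:
                d[t] = d_new
                offset[idx] = offset[idx] + coef * step
                if burn:
                    a_d[t] += 1

        if burn and (it + 1) % _ADAPT_BATCH == 0:
            _adapt(s_mu, a_mu, _ADAPT_BATCH)
            _adapt(s_d, a_d, _ADAPT_BATCH)
            a_mu[:] = 0
            a_d[:] = 0
        if not burn and (it - mcmc.burn_in) % mcmc.thin == 0 and kept < n_keep:
            out_d[kept] = d
            kept += 1
    return out_d[:kept], np.zeros(kept)


def _seed_list(seed) -> list[int]:
    if seed is None:
        return [0]
    if isinstance(seed, (int, np.integer)):
        return [int(seed)]
    return [int(s) for s in seed]


def fit_mtc(
    net: TrialNetwork,
    model: MTCModelSpec = MTCModelSpec(),
    mcmc: MCMCConfig = MCMCConfig(),
) -> PosteriorSamples:
    """Sample the MTC posterior for a connected network with responses set.

    Deterministic given ``mcmc.seed``; chain ``c`` uses the independent
    substream ``(seed, c)``.
    """
    model.validate()
    mcmc.validate()
    if not net.has_responses:
        raise ValueError("network has arms without responder counts; fill responses first")
    report = validate_network(net)
    if not report.is_valid:
        raise ValueError(str(report))
    design = _Design(net)
    runner = _run_chain_fe if model.sigma_fixed == 0 else _run_chain_re
    d_chains, s_chains = [], []
    base = _seed_list(mcmc.seed)
    for c in range(mcmc.chains):
        rng = np.random.default_rng(base + [c, 9157])
        dd, ss = runner(design, model, mcmc, rng)
        d_chains.append(dd)
        s_chains.append(ss)
    return PosteriorSamples(
        treatments=list(net.treatments),
        d=np.stack(d_chains),
        sigma=np.stack(s_chains),
    )


# ---------------------------------------------------------------------------
# posterior summaries
# ---------------------------------------------------------------------------


def single_contrast(
    post: PosteriorSamples,
    s: str,
    t: str,
    alpha: float = 0.05,
    rule: str = "normal",
) -> ContrastEstimate:
    """Contrast of ``t`` relative to ``s`` (log-OR > 0 favors ``t``)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha {alpha} outside (0, 1)")
    if rule not in ("normal", "credible"):
        raise ValueError(f"unknown significance rule {rule!r}")
    draws = post.contrast_draws(s, t)
    mean = float(draws.mean())
    sd = float(draws.std(ddof=1))
    if rule == "normal":
        z = norm.ppf(1.0 - alpha / 2.0)
        lo, hi = np.exp(mean - z * sd), np.exp(mean + z * sd)
    else:
        qlo, qhi = np.quantile(draws, [alpha / 2.0, 1.0 - alpha / 2.0])
        lo, hi = np.exp(qlo), np.exp(qhi)
    return ContrastEstimate(
        pair=(s, t),
        log_or=mean,
        se=sd,
        odds_ratio=float(np.exp(mean)),
        ci_low=float(lo),
        ci_high=float(hi),
        significant=bool(lo > 1.0 or hi < 1.0),
    )


def contrast_estimates(
    post: PosteriorSamples,
    alpha: float = 0.05,
    rule: str = "normal",
) -> list[ContrastEstimate]:
    """All k(k-1)/2 unordered pairwise contrasts.

    Convention: pair ``(s, t)`` with ``s`` before ``t`` in the network's
    treatment order reports the effect of ``t`` relative to ``s``.  The
    ``normal`` rule builds the 95% interval as ``exp(mean +/- z * sd)`` of
    the pooled log-OR draws; ``credible`` uses equal-tailed sample
    quantiles.  A contrast is significant iff its interval excludes OR = 1.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha {alpha} outside (0, 1)")
    if rule not in ("normal", "credible"):
        raise ValueError(f"unknown significance rule {rule!r}")
    eff = post.effect_draws()
    k = post.k
    z = norm.ppf(1.0 - alpha / 2.0)
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            draws = eff[:, j] - eff[:, i]
            mean = float(draws.mean())
            sd = float(draws.std(ddof=1))
            if rule == "normal":
                lo, hi = np.exp(mean - z * sd), np.exp(mean + z * sd)
            else:
                qlo, qhi = np.quantile(draws, [alpha / 2.0, 1.0 - alpha / 2.0])
                lo, hi = np.exp(qlo), np.exp(qhi)
            out.append(
                ContrastEstimate(
                    pair=(post.treatments[i], post.treatments[j]),
                    log_or=mean,
                    se=sd,
                    odds_ratio=float(np.exp(mean)),
                    ci_low=float(lo),
                    ci_high=float(hi),
                    significant=bool(lo > 1.0 or hi < 1.0),
                )
            )
    return out


def contrast_table(contrasts: Sequence[ContrastEstimate]) -> pd.DataFrame:
    """Contrast list as a DataFrame matching the on-disk CSV layout."""
    return pd.DataFrame(
        {
            "pair": [f"{c.pair[0]}:{c.pair[1]}" for c in contrasts],
            "logOR_mean": [c.log_or for c in contrasts],
            "logOR_sd": [c.se for c in contrasts],
            "OR": [c.odds_ratio for c in contrasts],
            "lo95": [c.ci_low for c in contrasts],
            "hi95": [c.ci_high for c in contrasts],
            "significant": [c.significant for c in contrasts],
        }
    )


def rank_probabilities(
    post: PosteriorSamples, higher_is_better: bool = True
) -> pd.DataFrame:
    """Posterior rank probabilities: entry (t, j) is the fraction of draws
    in which treatment t holds rank j (rank 1 = best)."""
    eff = post.effect_draws()
    signed = -eff if higher_is_better else eff
    ranks = np.argsort(np.argsort(signed, axis=1), axis=1)  # 0 = best
    k = post.k
    mat = np.stack([(ranks == j).mean(axis=0) for j in range(k)], axis=1)
    return pd.DataFrame(mat, index=post.treatments, columns=np.arange(1, k + 1))


@dataclass
class DiagnosticsReport:
    """Per-parameter PSRF (split-Rhat) and effective sample size."""

    table: pd.DataFrame
    max_psrf: float
    degenerate: bool = False

    @property
    def flagged(self) -> bool:
        return bool(np.isnan(self.max_psrf) or self.max_psrf > 1.05)


def convergence_diagnostics(post: PosteriorSamples) -> DiagnosticsReport:
    """Split-Rhat and bulk ESS per basic parameter (and sigma when sampled).

    Requires at least two chains.  Identical chains (e.g. a shared seed)
    make between-chain variance degenerate; the report flags this instead
    of pretending the diagnostic is informative.
    """
    if post.n_chains < 2:
        raise ValueError("convergence diagnostics require at least 2 chains")
    import arviz as az

    names = [f"d[{t}]" for t in post.treatments[1:]]
    series = [post.d[:, :, i] for i in range(post.k - 1)]
    if np.ptp(post.sigma) > 0:
        names.append("sigma")
        series.append(post.sigma)
    degenerate = all(
        np.allclose(s[0], s[c]) for s in series for c in range(1, post.n_chains)
    )
    rows = []
    for name, s in zip(names, series):
        da = az.convert_to_dataset({"x": s})
        rows.append(
            {
                "parameter": name,
                "psrf": float(az.rhat(da)["x"].values),
                "ess": float(az.ess(da)["x"].values),
            }
        )
    table = pd.DataFrame(rows)
    return DiagnosticsReport(
        table=table, max_psrf=float(table["psrf"].max()), degenerate=degenerate
    )
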