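"""Bayesian estimation of the hierarchical response / response-time models.

Fits one of three models to a :class:`~sathm.models.Dataset` by MCMC:

* ``"M0"``    — traditional hierarchical model: independent 2PL response and
  lognormal response-time submodels, linked only through the person-level
  correlation and the item-level covariance;
* ``"RMHM"``  — response moderation: the standardized residual log-time enters
  the 2PL linear predictor (``a*theta - b + alpha*Z``);
* ``"SATHM"`` — speed-accuracy tradeoff: the 2PL asymptote is attenuated by
  the time factor ``1 - exp(-exp(alpha*Z + zeta))``.

All three share the lognormal response-time submodel and the hierarchical
structure; they differ only in the response submodel.

Priors: ``a_j``, ``1/sigma_j``, ``alpha_j`` ~ N(0,1) truncated to (0, inf)
(the truncation of alpha can be lifted via ``MCMCConfig.truncate_alpha``);
``zeta`` ~ N(0,1); ``sigma_theta_tau`` ~ N(0,1) truncated to (-1, 1);
``(b_j, beta_j) | mu, Sigma_I`` ~ bivariate normal; ``Sigma_I`` ~
inverse-Wishart(I_2, 2); ``mu_b, mu_beta`` ~ N(0, 1000) (vague).
Identification is enforced by construction: the person-level means are fixed
at 0 and the variances at 1, so ``sigma_theta_tau`` is a correlation.

The sampler is Metropolis-within-Gibbs: adaptive random-walk Metropolis
updates (vectorized across persons / items) for all non-conjugate blocks, and
exact conjugate draws for ``(mu_b, mu_beta)`` (normal) and ``Sigma_I``
(inverse-Wishart).  Proposal scales adapt toward an acceptance rate of 0.44
during burn-in and are frozen afterwards.  Initialization is deterministic
(method-of-moments from the data), so a run is exactly reproducible from
(dataset, model, config).

Deviance is tracked at every retained draw under two conventions — the joint
conditional likelihood of responses and response times (default, which makes
the three models comparable) and the response-only likelihood — and DIC is
reported for both.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.special import expit, log_expit, ndtri
from scipy.stats import invwishart

from .models import Dataset, HyperParams, ItemParams, PersonParams, TestParams, log_time_factor

__all__ = ["MCMCConfig", "PosteriorResult", "log_joint", "run_mcmc", "psrf", "dic", "MODELS"]

MODELS = ("SATHM", "RMHM", "M0")

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)
_HALF_LOG_2 = math.log(2.0)
_MU_PRIOR_VAR = 1000.0  # vague normal hyperprior for (mu_b, mu_beta)


# ---------------------------------------------------------------------------
# configuration & results
# ---------------------------------------------------------------------------


@dataclass
class MCMCConfig:
    """Sampler settings.

    Defaults mirror the standard long-run protocol (30000 iterations, 10000
    burn-in, 2 chains, thinning 2); reduced settings are routinely used for
    simulation studies.
    """

    n_iter: int = 30000
    burn_in: int = 10000
    n_chains: int = 2
    thin: int = 2
    seed: int = 0
    adapt_window: int = 50
    target_accept: float = 0.44
    truncate_alpha: bool = True
    proposal_scales: Optional[dict] = None

    def __post_init__(self):
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("require 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")

    @property
    def n_retained(self) -> int:
        return -(-(self.n_iter - self.burn_in) // self.thin)  # ceil division


@dataclass
class PosteriorResult:
    """Posterior draws, summaries, convergence diagnostics and DIC."""

    model: str
    config: MCMCConfig
    chains: dict
    posterior_means: dict
    summary: pd.DataFrame
    mpsrf: float
    acceptance: dict
    deviance: dict  # per-convention: dbar, p_d, dic, deviance_at_mean
    converged: bool
    metadata: dict = field(default_factory=dict)

    @property
    def dic(self) -> float:
        """DIC under the joint (responses + response times) deviance."""
        return self.deviance["joint"]["dic"]


# ---------------------------------------------------------------------------
# likelihood / prior pieces
# ---------------------------------------------------------------------------


def _resp_ll_satm(u1, u0, loglam, log_a):
    llp = np.minimum(loglam + log_a, -1e-16)
    return u1 * llp + u0 * np.log1p(-np.exp(llp))


def _resp_ll_logistic(u1, u0, lin):
    return u1 * log_expit(lin) + u0 * log_expit(-lin)


def _log_trunc_pos(x):
    """log density of N(0,1) truncated to (0, inf); -inf outside support."""
    x = np.asarray(x, dtype=float)
    out = np.where(x > 0, _HALF_LOG_2 - _LOG_SQRT_2PI - 0.5 * x * x, -np.inf)
    return out


def _log_sigma_prior(sigma):
    """Prior on sigma implied by 1/sigma ~ N(0,1)I(0,inf), with Jacobian."""
    sigma = np.asarray(sigma, dtype=float)
    with np.errstate(divide="ignore"):
        val = _HALF_LOG_2 - _LOG_SQRT_2PI - 0.5 / (sigma * sigma) - 2.0 * np.log(sigma)
    return np.where(sigma > 0, val, -np.inf)


_RHO_TRUNC_CONST = math.log(0.682689492137086)  # P(-1 < N(0,1) < 1)


def _log_rho_prior(rho):
    if not -1.0 < rho < 1.0:
        return -np.inf
    return -_LOG_SQRT_2PI - 0.5 * rho * rho - _RHO_TRUNC_CONST


def _person_prior_terms(theta, tau, rho):
    """Elementwise bivariate-normal log prior of (theta, tau), unit margins."""
    c = 1.0 - rho * rho
    quad = (theta * theta - 2.0 * rho * theta * tau + tau * tau) / c
    return -0.5 * quad - 0.5 * math.log(c) - 2.0 * _LOG_SQRT_2PI


def _item_prior_terms(b, beta, mu, prec):
    """Elementwise bivariate-normal log prior of (b_j, beta_j)."""
    db = b - mu[0]
    dbeta = beta - mu[1]
    quad = prec[0, 0] * db * db + 2.0 * prec[0, 1] * db * dbeta + prec[1, 1] * dbeta * dbeta
    _, logdet_prec = np.linalg.slogdet(prec)
    return -0.5 * quad + 0.5 * logdet_prec - 2.0 * _LOG_SQRT_2PI


def log_joint(
    dataset: Dataset,
    item: ItemParams,
    test: TestParams,
    person: PersonParams,
    hyper: HyperParams,
    model: str = "SATHM",
    truncate_alpha: bool = True,
    response_likelihood: bool = True,
) -> float:
    """Unnormalized log posterior density of the full parameter set.

    Sum of the response likelihood under ``model``, the lognormal
    response-time likelihood, the person- and item-level hierarchical priors,
    and the parameter priors.  Returns ``-inf`` for out-of-support values
    rather than raising, so samplers can use it for rejection.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model tag {model!r}")
    a, b, beta, sigma, alpha = item.a, item.b, item.beta, item.sigma, item.alpha
    theta, tau = person.theta, person.tau
    rho = hyper.sigma_theta_tau

    if np.any(a <= 0) or np.any(sigma <= 0) or not -1 < rho < 1:
        return -np.inf
    if truncate_alpha and model != "M0" and np.any(alpha <= 0):
        return -np.inf
    try:
        prec = np.linalg.inv(hyper.Sigma_I)
    except np.linalg.LinAlgError:
        return -np.inf
    if np.any(np.linalg.eigvalsh(hyper.Sigma_I) <= 0):
        return -np.inf

    w = dataset.mask.astype(float)
    u1 = dataset.responses * w
    u0 = (1.0 - dataset.responses) * w
    log_t = np.where(dataset.mask, np.log(np.where(dataset.mask, dataset.times, 1.0)), 0.0)

    z = (log_t - (beta[None, :] - tau[:, None])) / sigma[None, :]
    rt_ll = (-_LOG_SQRT_2PI - np.log(sigma)[None, :] - 0.5 * z * z - log_t) * w

    total = float(rt_ll.sum())
    if response_likelihood:
        eta = theta[:, None] * a[None, :] - b[None, :]
        if model == "M0":
            resp = _resp_ll_logistic(u1, u0, eta)
        elif model == "RMHM":
            resp = _resp_ll_logistic(u1, u0, eta + alpha[None, :] * z)
        else:
            resp = _resp_ll_satm(u1, u0, log_expit(eta), log_time_factor(alpha[None, :] * z + test.zeta))
        total += float(resp.sum())

    # hierarchical priors
    total += float(_person_prior_terms(theta, tau, rho).sum())
    total += float(_item_prior_terms(b, beta, np.array([hyper.mu_b, hyper.mu_beta]), prec).sum())

    # parameter priors
    total += float(_log_trunc_pos(a).sum())
    total += float(_log_sigma_prior(sigma).sum())
    if truncate_alpha:
        total += float(_log_trunc_pos(alpha).sum())
    else:
        total += float((-_LOG_SQRT_2PI - 0.5 * alpha * alpha).sum())
    total += -_LOG_SQRT_2PI - 0.5 * test.zeta**2
    total += _log_rho_prior(rho)
    total += float(invwishart.logpdf(hyper.Sigma_I, 2, np.eye(2)))
    total += float(
        (-0.5 * math.log(2 * math.pi * _MU_PRIOR_VAR) - 0.5 * np.array([hyper.mu_b, hyper.mu_beta]) ** 2 / _MU_PRIOR_VAR).sum()
    )
    return total


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------


def psrf(chains: np.ndarray) -> float:
    """Brooks–Gelman multivariate potential scale reduction factor.

    ``chains`` has shape (n_chains, n_draws, n_params) (a 2-D input is treated
    as a single parameter).  Values near 1 indicate between-chain agreement;
    > 1.1 is conventionally taken as non-convergence.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim == 2:
        chains = chains[:, :, None]
    if chains.ndim != 3:
        raise ValueError("chains must be (n_chains, n_draws, n_params)")
    m, n, p = chains.shape
    if m < 2:
        raise ValueError("psrf requires at least 2 chains")
    if n < 10:
        raise ValueError("psrf requires at least 10 draws per chain")

    w = np.zeros((p, p))
    means = chains.mean(axis=1)
    for c in range(m):
        d = chains[c] - means[c]
        w += d.T @ d / (n - 1)
    w /= m
    gm = means.mean(axis=0)
    dm = means - gm
    b_over_n = dm.T @ dm / (m - 1)

    try:
        lam = linalg.eigh(b_over_n, w, eigvals_only=True)[-1]
    except linalg.LinAlgError:
        lam = np.max(np.real(np.linalg.eigvals(np.linalg.pinv(w) @ b_over_n)))
    return float((n - 1) / n + (m + 1) / m * max(lam, 0.0))


def dic(deviance_draws, deviance_at_mean: float):
    """DIC from MCMC deviance samples.

    ``D_bar`` is the posterior mean deviance (-2 log-likelihood), ``p_D =
    D_bar - D(mean)`` the effective number of parameters, and ``DIC = D_bar +
    p_D``.  Returns ``(D_bar, p_D, DIC)``.
    """
    draws = np.asarray(deviance_draws, dtype=float)
    if draws.size == 0:
        raise ValueError("deviance_draws must be nonempty")
    if not (np.all(np.isfinite(draws)) and np.isfinite(deviance_at_mean)):
        raise ValueError("deviances must be finite")
    d_bar = float(draws.mean())
    p_d = d_bar - float(deviance_at_mean)
    return d_bar, p_d, d_bar + p_d


# ---------------------------------------------------------------------------
# the Metropolis-within-Gibbs chain
# ---------------------------------------------------------------------------


class _Chain:
    """One MCMC chain; vectorized block updates with cached likelihood terms."""

    def __init__(self, dataset: Dataset, model: str, config: MCMCConfig, rng: np.random.Generator, response_likelihood: bool = True):
        self.model = model
        self.cfg = config
        self.rng = rng
        self.resp_lik_on = response_likelihood

        self.n, self.m = dataset.n_persons, dataset.n_items
        self.w = dataset.mask.astype(float)
        self.complete = bool(dataset.mask.all())
        self.u1 = dataset.responses * self.w
        self.u0 = (1.0 - dataset.responses) * self.w
        if not response_likelihood:
            self.u1 = np.zeros_like(self.u1)
            self.u0 = np.zeros_like(self.u0)
        self.log_t = np.where(dataset.mask, np.log(np.where(dataset.mask, dataset.times, 1.0)), 0.0)
        # constant part of the lognormal density (Jacobian + normalizing const)
        self.rt_const = float((-(self.log_t + _LOG_SQRT_2PI) * self.w).sum())

        self._init_state(dataset)
        self._init_scales()
        self._refresh_caches()

    # -- initialization ---------------------------------------------------

    def _init_state(self, dataset: Dataset):
        w, log_t = self.w, self.log_t
        n_obs_row = np.maximum(w.sum(axis=1), 1.0)
        n_obs_col = np.maximum(w.sum(axis=0), 1.0)

        score = (dataset.responses * w).sum(axis=1) / n_obs_row
        theta = score - score.mean()
        sd = theta.std()
        self.theta = theta / sd if sd > 1e-8 else np.zeros(self.n)

        beta0 = (log_t * w).sum(axis=0) / n_obs_col
        tau = beta0.mean() - (log_t * w).sum(axis=1) / n_obs_row
        tau = tau - tau.mean()
        sd = tau.std()
        self.tau = tau / sd if sd > 1e-8 else np.zeros(self.n)
        self.beta = beta0

        resid = (log_t + self.tau[:, None] - beta0[None, :]) * w
        var = (resid**2).sum(axis=0) / n_obs_col
        self.sigma = np.clip(np.sqrt(var), 0.2, 10.0)

        p_col = np.clip((dataset.responses * w).sum(axis=0) / n_obs_col, 0.05, 0.95)
        self.a = np.ones(self.m)
        self.b = -np.log(p_col / (1 - p_col))
        self.alpha = np.full(self.m, 0.5)
        self.zeta = 0.5
        if self.n > 2 and self.theta.std() > 0 and self.tau.std() > 0:
            self.rho = float(np.clip(np.corrcoef(self.theta, self.tau)[0, 1], -0.9, 0.9))
        else:
            self.rho = 0.0
        self.mu = np.array([self.b.mean(), self.beta.mean()])
        x = np.stack([self.b, self.beta], axis=1)
        self.Sigma_I = np.cov(x.T) + 0.1 * np.eye(2) if self.m > 2 else np.eye(2)
        self.prec_I = np.linalg.inv(self.Sigma_I)

    def _init_scales(self):
        base = {
            "theta": np.full(self.n, 0.5),
            "tau": np.full(self.n, 0.3),
            "a": np.full(self.m, 0.3),
            "b": np.full(self.m, 0.3),
            "beta": np.full(self.m, 0.1),
            "sigma": np.full(self.m, 0.2),
            "alpha": np.full(self.m, 0.3),
            "zeta": np.array([0.1]),
            "rho": np.array([0.05]),
        }
        if self.cfg.proposal_scales:
            for k, v in self.cfg.proposal_scales.items():
                base[k] = np.broadcast_to(np.asarray(v, float), base[k].shape).copy()
        self.scales = base
        self.acc_win = {k: np.zeros_like(v) for k, v in base.items()}
        self.acc_post = {k: 0.0 for k in base}
        self.acc_post_n = 0
        self.batch = 1

    # -- cached likelihood matrices --------------------------------------

    def _refresh_caches(self):
        self.eta = self.theta[:, None] * self.a[None, :] - self.b[None, :]
        self.z = (self.log_t - (self.beta[None, :] - self.tau[:, None])) / self.sigma[None, :]
        self.rt_ll = (-np.log(self.sigma)[None, :] - 0.5 * self.z * self.z) * self.w
        if self.model == "SATHM":
            self.loglam = log_expit(self.eta)
            self.log_a_cache = log_time_factor(self.alpha[None, :] * self.z + self.zeta)
        self.resp_ll = self._resp_full(self.eta, self.z)

    def _resp_full(self, eta, z):
        if not self.resp_lik_on:
            return np.zeros_like(eta)
        if self.model == "M0":
            return _resp_ll_logistic(self.u1, self.u0, eta)
        if self.model == "RMHM":
            return _resp_ll_logistic(self.u1, self.u0, eta + self.alpha[None, :] * z)
        return _resp_ll_satm(self.u1, self.u0, self.loglam, self.log_a_cache)

    def _resp_from_eta(self, eta):
        """Response log-lik when only the 2PL linear predictor changed.

        Returns (resp_ll, loglam) with loglam non-None only for SATHM, so the
        caller can refresh the cached log-asymptote on accepted coordinates.
        """
        if not self.resp_lik_on:
            return self.resp_ll, None
        if self.model == "M0":
            return _resp_ll_logistic(self.u1, self.u0, eta), None
        if self.model == "RMHM":
            return _resp_ll_logistic(self.u1, self.u0, eta + self.alpha[None, :] * self.z), None
        loglam = log_expit(eta)
        return _resp_ll_satm(self.u1, self.u0, loglam, self.log_a_cache), loglam

    def _resp_from_z(self, z):
        """Response log-lik when only Z changed (tau / beta / sigma updates)."""
        if not self.resp_lik_on or self.model == "M0":
            return self.resp_ll, None
        if self.model == "RMHM":
            return _resp_ll_logistic(self.u1, self.u0, self.eta + self.alpha[None, :] * z), None
        log_a = log_time_factor(self.alpha[None, :] * z + self.zeta)
        return _resp_ll_satm(self.u1, self.u0, self.loglam, log_a), log_a

    # -- block updates ----------------------------------------------------

    def _accept_rows(self, key, accept):
        self.acc_win[key] += accept
        if self._post_burn:
            self.acc_post[key] += accept.mean()

    def _update_theta(self):
        prop = self.theta + self.scales["theta"] * self.rng.standard_normal(self.n)
        eta_p = prop[:, None] * self.a[None, :] - self.b[None, :]
        resp_p, loglam_p = self._resp_from_eta(eta_p)
        delta = (resp_p - self.resp_ll).sum(axis=1)
        delta += _person_prior_terms(prop, self.tau, self.rho) - _person_prior_terms(self.theta, self.tau, self.rho)
        acc = np.log(self.rng.uniform(size=self.n)) < delta
        self.theta = np.where(acc, prop, self.theta)
        self.eta[acc] = eta_p[acc]
        self.resp_ll[acc] = resp_p[acc]
        if loglam_p is not None:
            self.loglam[acc] = loglam_p[acc]
        self._accept_rows("theta", acc)

    def _update_tau(self):
        prop = self.tau + self.scales["tau"] * self.rng.standard_normal(self.n)
        d = (prop - self.tau)[:, None] / self.sigma[None, :]
        z_p = self.z + d
        rt_p = (-np.log(self.sigma)[None, :] - 0.5 * z_p * z_p) * self.w
        resp_p, log_a_p = self._resp_from_z(z_p)
        delta = (rt_p - self.rt_ll).sum(axis=1)
        if resp_p is not self.resp_ll:
            delta += (resp_p - self.resp_ll).sum(axis=1)
        delta += _person_prior_terms(self.theta, prop, self.rho) - _person_prior_terms(self.theta, self.tau, self.rho)
        acc = np.log(self.rng.uniform(size=self.n)) < delta
        self.tau = np.where(acc, prop, self.tau)
        self.z[acc] = z_p[acc]
        self.rt_ll[acc] = rt_p[acc]
        if resp_p is not self.resp_ll:
            self.resp_ll[acc] = resp_p[acc]
        if log_a_p is not None:
            self.log_a_cache[acc] = log_a_p[acc]
        self._accept_rows("tau", acc)

    def _update_a(self):
        prop = self.a + self.scales["a"] * self.rng.standard_normal(self.m)
        valid = prop > 0
        prop = np.where(valid, prop, self.a)
        eta_p = self.theta[:, None] * prop[None, :] - self.b[None, :]
        resp_p, loglam_p = self._resp_from_eta(eta_p)
        delta = (resp_p - self.resp_ll).sum(axis=0)
        delta += -0.5 * (prop * prop - self.a * self.a)
        delta = np.where(valid, delta, -np.inf)
        acc = np.log(self.rng.uniform(size=self.m)) < delta
        self.a = np.where(acc, prop, self.a)
        self.eta[:, acc] = eta_p[:, acc]
        self.resp_ll[:, acc] = resp_p[:, acc]
        if loglam_p is not None:
            self.loglam[:, acc] = loglam_p[:, acc]
        self._accept_rows("a", acc)

    def _update_b(self):
        prop = self.b + self.scales["b"] * self.rng.standard_normal(self.m)
        eta_p = self.eta - (prop - self.b)[None, :]
        resp_p, loglam_p = self._resp_from_eta(eta_p)
        delta = (resp_p - self.resp_ll).sum(axis=0)
        delta += _item_prior_quad_diff(prop, self.beta, self.b, self.beta, self.mu, self.prec_I)
        acc = np.log(self.rng.uniform(size=self.m)) < delta
        self.b = np.where(acc, prop, self.b)
        self.eta[:, acc] = eta_p[:, acc]
        self.resp_ll[:, acc] = resp_p[:, acc]
        if loglam_p is not None:
            self.loglam[:, acc] = loglam_p[:, acc]
        self._accept_rows("b", acc)

    def _update_beta(self):
        prop = self.beta + self.scales["beta"] * self.rng.standard_normal(self.m)
        z_p = self.z - ((prop - self.beta) / self.sigma)[None, :]
        rt_p = (-np.log(self.sigma)[None, :] - 0.5 * z_p * z_p) * self.w
        resp_p, log_a_p = self._resp_from_z(z_p)
        delta = (rt_p - self.rt_ll).sum(axis=0)
        if resp_p is not self.resp_ll:
            delta += (resp_p - self.resp_ll).sum(axis=0)
        delta += _item_prior_quad_diff(self.b, prop, self.b, self.beta, self.mu, self.prec_I)
        acc = np.log(self.rng.uniform(size=self.m)) < delta
        self.beta = np.where(acc, prop, self.beta)
        self.z[:, acc] = z_p[:, acc]
        self.rt_ll[:, acc] = rt_p[:, acc]
        if resp_p is not self.resp_ll:
            self.resp_ll[:, acc] = resp_p[:, acc]
        if log_a_p is not None:
            self.log_a_cache[:, acc] = log_a_p[:, acc]
        self._accept_rows("beta", acc)

    def _update_sigma(self):
        # multiplicative random walk on sigma (log-scale proposal)
        step = self.scales["sigma"] * self.rng.standard_normal(self.m)
        prop = self.sigma * np.exp(step)
        z_p = self.z * (self.sigma / prop)[None, :]
        rt_p = (-np.log(prop)[None, :] - 0.5 * z_p * z_p) * self.w
        resp_p, log_a_p = self._resp_from_z(z_p)
        delta = (rt_p - self.rt_ll).sum(axis=0)
        if resp_p is not self.resp_ll:
            delta += (resp_p - self.resp_ll).sum(axis=0)
        delta += _log_sigma_prior(prop) - _log_sigma_prior(self.sigma)
        delta += step  # Hastings correction for the multiplicative proposal
        acc = np.log(self.rng.uniform(size=self.m)) < delta
        self.sigma = np.where(acc, prop, self.sigma)
        self.z[:, acc] = z_p[:, acc]
        self.rt_ll[:, acc] = rt_p[:, acc]
        if resp_p is not self.resp_ll:
            self.resp_ll[:, acc] = resp_p[:, acc]
        if log_a_p is not None:
            self.log_a_cache[:, acc] = log_a_p[:, acc]
        self._accept_rows("sigma", acc)

    def _alpha_log_prior(self, alpha):
        if self.cfg.truncate_alpha:
            return np.where(alpha > 0, -0.5 * alpha * alpha, -np.inf)
        return -0.5 * alpha * alpha

    def _update_alpha(self):
        if self.model == "M0" or not self.resp_lik_on:
            # no likelihood contribution: draw directly from the prior
            if self.cfg.truncate_alpha:
                self.alpha = ndtri(0.5 + 0.5 * self.rng.uniform(size=self.m))
            else:
                self.alpha = self.rng.standard_normal(self.m)
            return
        prop = self.alpha + self.scales["alpha"] * self.rng.standard_normal(self.m)
        if self.model == "RMHM":
            resp_p = _resp_ll_logistic(self.u1, self.u0, self.eta + prop[None, :] * self.z)
            log_a_p = None
        else:
            log_a_p = log_time_factor(prop[None, :] * self.z + self.zeta)
            resp_p = _resp_ll_satm(self.u1, self.u0, self.loglam, log_a_p)
        delta = (resp_p - self.resp_ll).sum(axis=0)
        delta += self._alpha_log_prior(prop) - self._alpha_log_prior(self.alpha)
        acc = np.log(self.rng.uniform(size=self.m)) < delta
        self.alpha = np.where(acc, prop, self.alpha)
        self.resp_ll[:, acc] = resp_p[:, acc]
        if log_a_p is not None:
            self.log_a_cache[:, acc] = log_a_p[:, acc]
        self._accept_rows("alpha", acc)

    def _update_zeta(self):
        if self.model != "SATHM" or not self.resp_lik_on:
            self.zeta = float(self.rng.standard_normal())
            return
        prop = self.zeta + float(self.scales["zeta"][0]) * float(self.rng.standard_normal())
        log_a_p = log_time_factor(self.alpha[None, :] * self.z + prop)
        resp_p = _resp_ll_satm(self.u1, self.u0, self.loglam, log_a_p)
        delta = float((resp_p - self.resp_ll).sum())
        delta += -0.5 * (prop * prop - self.zeta * self.zeta)
        acc = math.log(self.rng.uniform()) < delta
        if acc:
            self.zeta = prop
            self.resp_ll = resp_p
            self.log_a_cache = log_a_p
        self._accept_rows("zeta", np.array([float(acc)]))

    def _update_rho(self):
        prop = self.rho + float(self.scales["rho"][0]) * float(self.rng.standard_normal())
        if not -1.0 < prop < 1.0:
            self._accept_rows("rho", np.array([0.0]))
            return
        s_tt = float(self.theta @ self.theta)
        s_uu = float(self.tau @ self.tau)
        s_tu = float(self.theta @ self.tau)

        def bvn_ll(r):
            c = 1.0 - r * r
            return -0.5 * self.n * math.log(c) - 0.5 * (s_tt - 2.0 * r * s_tu + s_uu) / c

        delta = bvn_ll(prop) - bvn_ll(self.rho)
        delta += -0.5 * (prop * prop - self.rho * self.rho)
        acc = math.log(self.rng.uniform()) < delta
        if acc:
            self.rho = prop
        self._accept_rows("rho", np.array([float(acc)]))

    def _update_mu(self):
        # conjugate bivariate-normal draw given (b, beta), Sigma_I
        x_sum = np.array([self.b.sum(), self.beta.sum()])
        prec = self.m * self.prec_I + np.eye(2) / _MU_PRIOR_VAR
        cov = np.linalg.inv(prec)
        mean = cov @ (self.prec_I @ x_sum)
        chol = np.linalg.cholesky(cov)
        self.mu = mean + chol @ self.rng.standard_normal(2)

    def _update_sigma_i(self):
        # conjugate inverse-Wishart draw given (b, beta), mu
        d = np.stack([self.b - self.mu[0], self.beta - self.mu[1]], axis=1)
        scale = np.eye(2) + d.T @ d
        self.Sigma_I = _invwishart_2x2(2 + self.m, scale, self.rng)
        self.prec_I = np.linalg.inv(self.Sigma_I)

    # -- adaptation & deviance --------------------------------------------

    def _adapt(self):
        step = min(0.5, 1.0 / math.sqrt(self.batch))
        for key, acc in self.acc_win.items():
            rate = acc / self.cfg.adapt_window
            self.scales[key] = np.clip(self.scales[key] * np.exp(step * (rate - self.cfg.target_accept)), 1e-3, 10.0)
            acc.fill(0.0)
        self.batch += 1

    def deviances(self):
        resp = float(self.resp_ll.sum())
        rt = float(self.rt_ll.sum()) + self.rt_const
        return -2.0 * (resp + rt), -2.0 * resp

    # -- main loop ---------------------------------------------------------

    def run(self):
        cfg = self.cfg
        n_keep = cfg.n_retained
        out = {
            "theta": np.empty((n_keep, self.n)),
            "tau": np.empty((n_keep, self.n)),
            "a": np.empty((n_keep, self.m)),
            "b": np.empty((n_keep, self.m)),
            "beta": np.empty((n_keep, self.m)),
            "sigma": np.empty((n_keep, self.m)),
            "alpha": np.empty((n_keep, self.m)),
            "zeta": np.empty(n_keep),
            "sigma_theta_tau": np.empty(n_keep),
            "mu_b": np.empty(n_keep),
            "mu_beta": np.empty(n_keep),
            "Sigma_I": np.empty((n_keep, 2, 2)),
            "deviance_joint": np.empty(n_keep),
            "deviance_resp": np.empty(n_keep),
        }
        k = 0
        self._post_burn = False
        for t in range(cfg.n_iter):
            self._post_burn = t >= cfg.burn_in
            self._update_theta()
            self._update_tau()
            self._update_a()
            self._update_b()
            self._update_beta()
            self._update_sigma()
            self._update_alpha()
            self._update_zeta()
            self._update_rho()
            self._update_mu()
            self._update_sigma_i()
            if self._post_burn:
                self.acc_post_n += 1
            if not self._post_burn and (t + 1) % cfg.adapt_window == 0:
                self._adapt()
            if self._post_burn and (t - cfg.burn_in) % cfg.thin == 0:
                out["theta"][k] = self.theta
                out["tau"][k] = self.tau
                out["a"][k] = self.a
                out["b"][k] = self.b
                out["beta"][k] = self.beta
                out["sigma"][k] = self.sigma
                out["alpha"][k] = self.alpha
                out["zeta"][k] = self.zeta
                out["sigma_theta_tau"][k] = self.rho
                out["mu_b"][k] = self.mu[0]
                out["mu_beta"][k] = self.mu[1]
                out["Sigma_I"][k] = self.Sigma_I
                dj, dr = self.deviances()
                out["deviance_joint"][k] = dj
                out["deviance_resp"][k] = dr
                k += 1
        assert k == n_keep, f"retained-draw bookkeeping failed in chain ({k} != {n_keep})"
        acc_rates = {key: val / max(self.acc_post_n, 1) for key, val in self.acc_post.items()}
        return out, acc_rates


def _invwishart_2x2(df: int, scale: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw from InvWishart(scale, df) for a 2x2 scale via Bartlett.

    X ~ Wishart(df, scale^-1) is drawn as L A A' L' with L = chol(scale^-1)
    and A the Bartlett factor; the inverse-Wishart draw is X^-1.
    """
    prec = np.linalg.inv(scale)
    ell = np.linalg.cholesky(prec)
    a11 = math.sqrt(rng.chisquare(df))
    a22 = math.sqrt(rng.chisquare(df - 1))
    a21 = rng.standard_normal()
    bart = np.array([[a11, 0.0], [a21, a22]])
    f = ell @ bart
    x = f @ f.T
    det = x[0, 0] * x[1, 1] - x[0, 1] * x[1, 0]
    return np.array([[x[1, 1], -x[0, 1]], [-x[1, 0], x[0, 0]]]) / det


def _item_prior_quad_diff(b_new, beta_new, b_old, beta_old, mu, prec):
    """Difference of bivariate-normal item-prior log densities (vectorized)."""

    def quad(b, beta):
        db = b - mu[0]
        dbeta = beta - mu[1]
        return prec[0, 0] * db * db + 2.0 * prec[0, 1] * db * dbeta + prec[1, 1] * dbeta * dbeta

    return -0.5 * (quad(b_new, beta_new) - quad(b_old, beta_old))


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

_PARAM_KEYS = ("theta", "tau", "a", "b", "beta", "sigma", "alpha", "zeta", "sigma_theta_tau", "mu_b", "mu_beta", "Sigma_I")


def run_mcmc(
    dataset: Dataset,
    model: str = "SATHM",
    config: Optional[MCMCConfig] = None,
    response_likelihood: bool = True,
) -> PosteriorResult:
    """Fit ``model`` to ``dataset`` by Metropolis-within-Gibbs MCMC.

    Runs ``config.n_chains`` independent chains from a deterministic
    initialization (chains differ only through their RNG streams, derived from
    ``config.seed``), discards ``config.burn_in`` iterations, thins, and
    returns draws, posterior summaries, the multivariate PSRF computed over
    the item-, test- and hyper-level parameters, acceptance rates, and DIC
    under both the joint and the response-only deviance conventions.

    A result with PSRF >= 1.1 is returned flagged (``converged=False``), not
    discarded.  ``response_likelihood=False`` fits the response-time submodel
    alone (used for sampler validation).
    """
    if model not in MODELS:
        raise ValueError(f"unknown model tag {model!r}; expected one of {MODELS}")
    if dataset.n_persons < 2 or dataset.n_items < 1:
        raise ValueError("dataset must contain at least 2 persons and 1 item")
    config = config or MCMCConfig()

    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    chain_draws = []
    acc_all = []
    for c in range(config.n_chains):
        chain = _Chain(dataset, model, config, np.random.default_rng(seeds[c]), response_likelihood)
        draws, acc = chain.run()
        chain_draws.append(draws)
        acc_all.append(acc)

    chains = {key: np.stack([d[key] for d in chain_draws]) for key in chain_draws[0]}
    post_means = {key: chains[key].mean(axis=(0, 1)) for key in _PARAM_KEYS}

    # deviance at the posterior means of all parameters (incl. persons)
    item = ItemParams(
        a=np.maximum(post_means["a"], 1e-8),
        b=post_means["b"],
        beta=post_means["beta"],
        sigma=np.maximum(post_means["sigma"], 1e-8),
        alpha=post_means["alpha"],
    )
    person = PersonParams(theta=post_means["theta"], tau=post_means["tau"])
    test = TestParams(zeta=float(post_means["zeta"]))
    dev_at_mean_joint, dev_at_mean_resp = _deviance_at(dataset, item, test, person, model, response_likelihood)

    deviance = {}
    for tag, draws_key, at_mean in (
        ("joint", "deviance_joint", dev_at_mean_joint),
        ("response", "deviance_resp", dev_at_mean_resp),
    ):
        d_bar, p_d, d_ic = dic(chains[draws_key].ravel(), at_mean)
        deviance[tag] = {"dbar": d_bar, "p_d": p_d, "dic": d_ic, "deviance_at_mean": at_mean}

    mpsrf = float("nan")
    if config.n_chains >= 2 and config.n_retained >= 10:
        try:
            mpsrf = psrf(_diagnostic_block(chains))
        except (linalg.LinAlgError, ValueError):
            mpsrf = float("nan")

    acceptance = {k: float(np.mean([a[k] for a in acc_all])) for k in acc_all[0]}
    summary = _summaries(chains)
    converged = bool(np.isfinite(mpsrf) and mpsrf < 1.1)
    return PosteriorResult(
        model=model,
        config=config,
        chains=chains,
        posterior_means=post_means,
        summary=summary,
        mpsrf=mpsrf,
        acceptance=acceptance,
        deviance=deviance,
        converged=converged,
        metadata={
            "deviance_convention": "joint conditional likelihood of responses and response times",
            "response_likelihood": response_likelihood,
        },
    )


def _deviance_at(dataset, item, test, person, model, response_likelihood):
    w = dataset.mask.astype(float)
    u1 = dataset.responses * w
    u0 = (1.0 - dataset.responses) * w
    log_t = np.where(dataset.mask, np.log(np.where(dataset.mask, dataset.times, 1.0)), 0.0)
    z = (log_t - (item.beta[None, :] - person.tau[:, None])) / item.sigma[None, :]
    rt = ((-_LOG_SQRT_2PI - np.log(item.sigma)[None, :] - 0.5 * z * z - log_t) * w).sum()
    if not response_likelihood:
        return -2.0 * float(rt), 0.0
    eta = person.theta[:, None] * item.a[None, :] - item.b[None, :]
    if model == "M0":
        resp = _resp_ll_logistic(u1, u0, eta)
    elif model == "RMHM":
        resp = _resp_ll_logistic(u1, u0, eta + item.alpha[None, :] * z)
    else:
        resp = _resp_ll_satm(u1, u0, log_expit(eta), log_time_factor(item.alpha[None, :] * z + test.zeta))
    resp = float(resp.sum())
    return -2.0 * (resp + float(rt)), -2.0 * resp


def _diagnostic_block(chains) -> np.ndarray:
    """Stack item-, test- and hyper-level draws as (n_chains, n_draws, p)."""
    pieces = [chains[k] for k in ("a", "b", "beta", "sigma", "alpha")]
    pieces += [chains[k][:, :, None] for k in ("zeta", "sigma_theta_tau", "mu_b", "mu_beta")]
    sig = chains["Sigma_I"]
    pieces.append(np.stack([sig[:, :, 0, 0], sig[:, :, 0, 1], sig[:, :, 1, 1]], axis=2))
    return np.concatenate(pieces, axis=2)


def _summaries(chains) -> pd.DataFrame:
    rows = []
    for key in _PARAM_KEYS:
        arr = chains[key]
        if key == "Sigma_I":
            flat = {
                "Sigma_I[b,b]": arr[:, :, 0, 0],
                "Sigma_I[b,beta]": arr[:, :, 0, 1],
                "Sigma_I[beta,beta]": arr[:, :, 1, 1],
            }
        elif arr.ndim == 2:
            flat = {key: arr}
        else:
            flat = {f"{key}[{j}]": arr[:, :, j] for j in range(arr.shape[2])}
        for name, draws in flat.items():
            v = draws.ravel()
            lo, hi = np.percentile(v, [2.5, 97.5])
            rows.append((name, v.mean(), v.std(ddof=1) if v.size > 1 else 0.0, lo, hi))
    return pd.DataFrame(rows, columns=["param", "mean", "sd", "ci_lower", "ci_upper"]).set_index("param")
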