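"""Synthetic data generation for the joint response / response-time models.

Generates person and item parameters from the hierarchical generating
distributions and then complete response-time and response matrices from the
chosen response model (SATHM by default; RMHM or the traditional hierarchical
model M0 for comparison studies).

Generating distributions (the defaults of :class:`SimDesign`):

* items: ``a_j``, ``1/sigma_j``, ``alpha_j`` ~ standard normal truncated to
  (0, inf); ``zeta`` ~ N(0, 1); ``(b_j, beta_j)`` ~ bivariate normal with mean
  (0, 3) and covariance [[1, 0.25], [0.25, 0.25]] (beta in log-seconds);
* persons: ``(theta_i, tau_i)`` ~ bivariate normal with means 0, variances 1
  (the identification restrictions) and correlation 0.5;
* data: ``ln T_ij ~ N(beta_j - tau_i, sigma_j^2)``, then ``Z_ij`` from the
  true parameters, then ``U_ij ~ Bernoulli(P_ij)`` under the generating model.

Truncated-normal draws use inverse-CDF sampling so that a seed reproduces the
same parameters on every platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, ndtri

from .models import (
    Dataset,
    HyperParams,
    ItemParams,
    PersonParams,
    TestParams,
    log_time_factor,
)

__all__ = ["SimDesign", "SimTruth", "draw_items", "draw_persons", "generate_dataset", "simulate"]

MODELS = ("SATHM", "RMHM", "M0")


@dataclass
class SimDesign:
    """Design of a simulation condition.

    Defaults follow the standard recovery-study grid: N in {500, 1000} persons,
    m in {30, 60} items, person correlation 0.5, item means (0, 3) and item
    covariance [[1, .25], [.25, .25]].
    """

    n_persons: int = 500
    n_items: int = 30
    sigma_theta_tau: float = 0.5
    item_mean: tuple = (0.0, 3.0)
    item_cov: np.ndarray = field(default_factory=lambda: np.array([[1.0, 0.25], [0.25, 0.25]]))
    generating_model: str = "SATHM"
    seed: int = 0

    def __post_init__(self):
        self.item_cov = np.asarray(self.item_cov, dtype=float)
        if self.n_persons < 1 or self.n_items < 1:
            raise ValueError("n_persons and n_items must be >= 1")
        if not -1.0 < self.sigma_theta_tau < 1.0:
            raise ValueError("sigma_theta_tau must lie in (-1, 1)")
        if self.item_cov.shape != (2, 2) or np.any(np.linalg.eigvalsh(self.item_cov) <= 0):
            raise ValueError("item_cov must be 2x2 positive definite")
        if self.generating_model not in MODELS:
            raise ValueError(f"generating_model must be one of {MODELS}")


@dataclass
class SimTruth:
    """Generating parameter values bundled for recovery scoring."""

    item: ItemParams
    test: TestParams
    person: PersonParams
    hyper: HyperParams
    design: SimDesign


def _truncnorm_pos(rng: np.random.Generator, size) -> np.ndarray:
    # standard normal truncated to (0, inf) via inverse CDF
    u = rng.uniform(size=size)
    return ndtri(0.5 + 0.5 * u)


def draw_items(design: SimDesign, rng: np.random.Generator):
    """Draw item parameters and the test-level intercept.

    ``sigma_j`` is stored as the reciprocal of the positive truncated-normal
    draw of ``1/sigma_j``, matching the prior used in estimation.
    """
    m = design.n_items
    a = _truncnorm_pos(rng, m)
    inv_sigma = _truncnorm_pos(rng, m)
    alpha = _truncnorm_pos(rng, m)
    zeta = float(rng.standard_normal())
    bb = rng.multivariate_normal(np.asarray(design.item_mean, dtype=float), design.item_cov, size=m)
    item = ItemParams(a=a, b=bb[:, 0], beta=bb[:, 1], sigma=1.0 / inv_sigma, alpha=alpha)
    return item, TestParams(zeta=zeta)


def draw_persons(design: SimDesign, rng: np.random.Generator) -> PersonParams:
    """Draw (theta, tau) bivariate normal, means 0, variances 1, correlation rho."""
    rho = design.sigma_theta_tau
    cov = np.array([[1.0, rho], [rho, 1.0]])
    x = rng.multivariate_normal(np.zeros(2), cov, size=design.n_persons)
    return PersonParams(theta=x[:, 0], tau=x[:, 1])


def response_probability(truth: SimTruth, z: np.ndarray) -> np.ndarray:
    """Per-cell probability of a correct response under the generating model."""
    item, person = truth.item, truth.person
    eta = person.theta[:, None] * item.a[None, :] - item.b[None, :]
    model = truth.design.generating_model
    if model == "M0":
        return expit(eta)
    if model == "RMHM":
        return expit(eta + item.alpha[None, :] * z)
    g = item.alpha[None, :] * z + truth.test.zeta
    return expit(eta) * np.exp(log_time_factor(g))


def generate_dataset(truth: SimTruth, rng: np.random.Generator) -> Dataset:
    """Generate complete response-time and response matrices from the truth.

    For every cell: draw ``ln T`` from the lognormal model, form the
    standardized residual Z from the true parameters, and draw the response
    from the generating model's probability.  No missingness is generated.
    """
    item, person, design = truth.item, truth.person, truth.design
    n, m = design.n_persons, design.n_items
    mean_lt = item.beta[None, :] - person.tau[:, None]
    log_t = mean_lt + rng.standard_normal((n, m)) * item.sigma[None, :]
    # exp() must stay within double range; the half-normal prior on 1/sigma
    # puts no lower bound on it, so astronomically large |lnT| can occur.
    log_t = np.clip(log_t, -700.0, 700.0)
    z = (log_t - mean_lt) / item.sigma[None, :]
    p = response_probability(truth, z)
    u = (rng.uniform(size=(n, m)) < p).astype(float)
    return Dataset(responses=u, times=np.exp(log_t))


def simulate(design: SimDesign, rng: np.random.Generator | None = None):
    """Draw a full truth and one dataset from it; returns (truth, dataset)."""
    if rng is None:
        rng = np.random.default_rng(design.seed)
    item, test = draw_items(design, rng)
    person = draw_persons(design, rng)
    hyper = HyperParams(
        sigma_theta_tau=design.sigma_theta_tau,
        mu_b=design.item_mean[0],
        mu_beta=design.item_mean[1],
        Sigma_I=design.item_cov,
    )
    truth = SimTruth(item=item, test=test, person=person, hyper=hyper, design=design)
    return truth, generate_dataset(truth, rng)
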