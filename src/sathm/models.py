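"""Closed-form layer: response and response-time models.

This module collects the probability models that the rest of the package is
built from:

* the two-parameter logistic (2PL) item response model with linear predictor
  ``a*theta - b`` (note: NOT ``a*(theta - b)``; both conventions exist in the
  IRT literature and they are not interchangeable),
* the lognormal response-time model ``ln T ~ N(beta - tau, sigma^2)``,
* the standardized residual log-time ``Z = (ln T - (beta - tau)) / sigma``,
* the speed-accuracy tradeoff (SAT) curve ``d(t) = lam*(1 - exp(-phi*(t - delta)))``
  and its least-squares fit to (time, accuracy) pairs,
* the SAT response model (SATM) ``P = lam * (1 - exp(-exp(alpha*Z + zeta)))``
  where ``lam`` is the 2PL asymptote, and
* the response-moderation model (RMM) ``P = logistic(a*theta - b + alpha*Z)``.

SATM is the 2PL attenuated by a time factor in (0, 1): accuracy rises toward
the 2PL asymptote as the (residual) response time grows, so a low-ability
person cannot reach high accuracy simply by responding slowly.  RMM lacks that
bound — its probability approaches 1 for any ability as ``alpha*Z`` grows.

All functions are vectorized over numpy arrays and numerically stable in
log-space for arguments up to |x| ~ 50.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.special import expit, log_expit

__all__ = [
    "ItemParams",
    "TestParams",
    "PersonParams",
    "HyperParams",
    "SATCurveParams",
    "SATCurveFit",
    "Dataset",
    "two_pl",
    "residual_z",
    "satm_prob",
    "rmm_prob",
    "satm_log_prob",
    "rmm_log_prob",
    "log_time_factor",
    "lognormal_rt_logpdf",
    "sat_curve",
    "fit_sat_curve",
]

# Clip for exp() in the double-exponential time factor; beyond this the
# factor is exactly 0.0 or 1.0 in double precision anyway.
_EXP_CLIP = 700.0
# Floor on log(1 - P): caps P at < 1 so Bernoulli log-likelihoods of
# incorrect responses stay finite even in asymptotic regimes.
_LOG_P_MAX = -1e-16


def _as_finite(x, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} must be finite")
    return x


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass
class ItemParams:
    """Per-item parameters.

    a : discrimination (> 0); b : difficulty; beta : time intensity, the
    item-level mean of log response time (log-seconds); sigma : residual SD of
    log time (> 0); alpha : slope of the residual-time effect on accuracy.
    """

    a: np.ndarray
    b: np.ndarray
    beta: np.ndarray
    sigma: np.ndarray
    alpha: np.ndarray

    def __post_init__(self):
        self.a = np.atleast_1d(np.asarray(self.a, dtype=float))
        self.b = np.atleast_1d(np.asarray(self.b, dtype=float))
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        self.sigma = np.atleast_1d(np.asarray(self.sigma, dtype=float))
        self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        n = {arr.shape for arr in (self.a, self.b, self.beta, self.sigma, self.alpha)}
        if len(n) != 1:
            raise ValueError("item parameter arrays must share length")
        if np.any(self.a <= 0):
            raise ValueError("discrimination a must be > 0")
        if np.any(self.sigma <= 0):
            raise ValueError("residual SD sigma must be > 0")

    @property
    def n_items(self) -> int:
        return self.a.shape[0]


@dataclass
class TestParams:
    """Test-level parameters: zeta, the intercept of the residual-time effect."""

    __test__ = False  # "Test" here means the instrument, not a pytest case

    zeta: float

    def __post_init__(self):
        self.zeta = float(self.zeta)
        if not np.isfinite(self.zeta):
            raise ValueError("zeta must be finite")


@dataclass
class PersonParams:
    """Per-person latent parameters: ability theta and speed tau."""

    theta: np.ndarray
    tau: np.ndarray

    def __post_init__(self):
        self.theta = np.atleast_1d(np.asarray(self.theta, dtype=float))
        self.tau = np.atleast_1d(np.asarray(self.tau, dtype=float))
        if self.theta.shape != self.tau.shape:
            raise ValueError("theta and tau must share length")

    @property
    def n_persons(self) -> int:
        return self.theta.shape[0]


@dataclass
class HyperParams:
    """Second-level parameters.

    The person means and variances are fixed (0 and 1) for identification, so
    the only free person-level quantity is the covariance ``sigma_theta_tau``,
    which equals the ability-speed correlation.  Items (b, beta) are jointly
    normal with mean ``(mu_b, mu_beta)`` and 2x2 covariance ``Sigma_I``.
    """

    sigma_theta_tau: float
    mu_b: float
    mu_beta: float
    Sigma_I: np.ndarray

    def __post_init__(self):
        self.sigma_theta_tau = float(self.sigma_theta_tau)
        self.mu_b = float(self.mu_b)
        self.mu_beta = float(self.mu_beta)
        self.Sigma_I = np.asarray(self.Sigma_I, dtype=float)
        if not -1.0 <= self.sigma_theta_tau <= 1.0:
            raise ValueError("sigma_theta_tau must lie in [-1, 1]")
        if self.Sigma_I.shape != (2, 2):
            raise ValueError("Sigma_I must be 2x2")
        if not np.allclose(self.Sigma_I, self.Sigma_I.T):
            raise ValueError("Sigma_I must be symmetric")
        if np.any(np.linalg.eigvalsh(self.Sigma_I) <= 0):
            raise ValueError("Sigma_I must be positive definite")

    @property
    def mu_item(self) -> np.ndarray:
        return np.array([self.mu_b, self.mu_beta])


@dataclass
class SATCurveParams:
    """Parameters of the exponential approach-to-asymptote accuracy curve.

    lam : asymptotic accuracy in (0, 1]; phi : rate of approach (1/seconds);
    delta : intercept time below which accuracy is at floor (seconds, >= 0).
    """

    lam: float
    phi: float
    delta: float

    def __post_init__(self):
        self.lam = float(self.lam)
        self.phi = float(self.phi)
        self.delta = float(self.delta)
        if not 0.0 < self.lam <= 1.0:
            raise ValueError("lam must lie in (0, 1]")
        if self.phi <= 0:
            raise ValueError("phi must be > 0")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")


@dataclass
class SATCurveFit:
    """Least-squares fit result for the SAT curve."""

    params: SATCurveParams
    rss: float
    converged: bool
    message: str = ""


@dataclass
class Dataset:
    """Paired binary responses and response times for N persons x J items.

    ``mask`` marks the observed cells; masked-out cells are ignored by every
    likelihood.  Times are in seconds and must be positive wherever observed.
    """

    responses: np.ndarray
    times: np.ndarray
    mask: np.ndarray = None
    person_ids: list = field(default=None)
    item_ids: list = field(default=None)

    def __post_init__(self):
        self.responses = np.asarray(self.responses, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.responses.ndim != 2 or self.times.shape != self.responses.shape:
            raise ValueError("responses and times must be 2-D with equal shape")
        if self.mask is None:
            self.mask = np.ones(self.responses.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.responses.shape:
                raise ValueError("mask shape mismatch")
        if np.any(self.times[self.mask] <= 0):
            raise ValueError("observed times must be > 0")
        obs = self.responses[self.mask]
        if not np.all(np.isin(obs, (0.0, 1.0))):
            raise ValueError("observed responses must be 0 or 1")
        n, m = self.responses.shape
        if self.person_ids is None:
            self.person_ids = [f"p{i+1}" for i in range(n)]
        if self.item_ids is None:
            self.item_ids = [f"i{j+1}" for j in range(m)]

    @property
    def n_persons(self) -> int:
        return self.responses.shape[0]

    @property
    def n_items(self) -> int:
        return self.responses.shape[1]


# ---------------------------------------------------------------------------
# response models
# ---------------------------------------------------------------------------


def two_pl(theta, a, b):
    """2PL probability of a correct response, ``expit(a*theta - b)``.

    This is the asymptotic ("time-unlimited") accuracy of the SAT response
    model.  Computed via ``expit`` so large |a*theta - b| cannot overflow.
    """
    theta = _as_finite(theta, "theta")
    a = _as_finite(a, "a")
    b = _as_finite(b, "b")
    if np.any(a <= 0):
        raise ValueError("discrimination a must be > 0")
    return expit(a * theta - b)


def residual_z(log_time, beta, tau, sigma):
    """Standardized residual log response time, ``(lnT - (beta - tau)) / sigma``.

    Positive Z means the response took longer than the model expects for this
    person-item pair; it is the driver of the tradeoff term in SATM/RMM.
    """
    log_time = _as_finite(log_time, "log_time")
    beta = _as_finite(beta, "beta")
    tau = _as_finite(tau, "tau")
    sigma = np.asarray(sigma, dtype=float)
    if np.any(~np.isfinite(sigma)) or np.any(sigma <= 0):
        raise ValueError("sigma must be finite and > 0")
    return (log_time - (beta - tau)) / sigma


def log_time_factor(g):
    """``log(1 - exp(-exp(g)))`` computed stably for any real g.

    This is the log of the SATM attenuation factor with ``g = alpha*Z + zeta``.
    The double exponential keeps the implied effective processing time
    positive; the factor rises from 0 to 1 as g grows.
    """
    g = np.clip(np.asarray(g, dtype=float), -_EXP_CLIP, _EXP_CLIP)
    return np.log(-np.expm1(-np.exp(g)))


def satm_log_prob(theta, a, b, alpha, z, zeta):
    """Log-probability of a correct response under the SAT response model."""
    eta = np.asarray(a, dtype=float) * theta - b
    g = np.asarray(alpha, dtype=float) * z + zeta
    return log_expit(eta) + log_time_factor(g)


def satm_prob(theta, a, b, alpha, z, zeta):
    """SAT response model probability.

    ``P = lam * (1 - exp(-exp(alpha*z + zeta)))`` with ``lam`` the 2PL
    probability.  P lies strictly between 0 and lam: for ample time
    (``z -> +inf`` with alpha > 0) the model reduces to the plain 2PL, while
    fast responding attenuates accuracy toward 0.
    """
    theta = _as_finite(theta, "theta")
    a = _as_finite(a, "a")
    b = _as_finite(b, "b")
    alpha = _as_finite(alpha, "alpha")
    z = _as_finite(z, "z")
    zeta = _as_finite(zeta, "zeta")
    if np.any(a <= 0):
        raise ValueError("discrimination a must be > 0")
    return np.exp(satm_log_prob(theta, a, b, alpha, z, zeta))


def rmm_log_prob(theta, a, b, alpha, z):
    return log_expit(np.asarray(a, dtype=float) * theta - b + np.asarray(alpha, dtype=float) * z)


def rmm_prob(theta, a, b, alpha, z):
    """Response-moderation model probability.

    The residual time enters the 2PL linear predictor directly:
    ``P = expit(a*theta - b + alpha*z)``.  Unlike SATM there is no
    ability-determined asymptote — P approaches 1 whenever ``alpha*z`` grows,
    regardless of theta.
    """
    theta = _as_finite(theta, "theta")
    a = _as_finite(a, "a")
    b = _as_finite(b, "b")
    alpha = _as_finite(alpha, "alpha")
    z = _as_finite(z, "z")
    if np.any(a <= 0):
        raise ValueError("discrimination a must be > 0")
    return np.exp(rmm_log_prob(theta, a, b, alpha, z))


# ---------------------------------------------------------------------------
# response-time model
# ---------------------------------------------------------------------------

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


def lognormal_rt_logpdf(time, beta, tau, sigma):
    """Log-density of the lognormal response-time model.

    ``ln T ~ N(beta - tau, sigma^2)``; the returned value is the density of T
    itself (normal log-density of ln T minus the ln T Jacobian), so
    ``exp(logpdf)`` integrates to 1 over T in (0, inf).
    """
    time = np.asarray(time, dtype=float)
    if np.any(~np.isfinite(time)) or np.any(time <= 0):
        raise ValueError("time must be finite and > 0")
    sigma = np.asarray(sigma, dtype=float)
    if np.any(~np.isfinite(sigma)) or np.any(sigma <= 0):
        raise ValueError("sigma must be finite and > 0")
    beta = _as_finite(beta, "beta")
    tau = _as_finite(tau, "tau")
    log_t = np.log(time)
    z = (log_t - (beta - tau)) / sigma
    return -_LOG_SQRT_2PI - np.log(sigma) - 0.5 * z * z - log_t


# ---------------------------------------------------------------------------
# SAT curve (experimental accuracy-vs-time form) and its least-squares fit
# ---------------------------------------------------------------------------


def sat_curve(t, params: SATCurveParams):
    """Accuracy at processing time t: ``lam * (1 - exp(-phi*(t - delta)))``.

    Defined for ``t > delta``; strictly increasing in t and approaching the
    asymptote lam as t -> inf.
    """
    t = _as_finite(t, "t")
    if np.any(t <= params.delta):
        raise ValueError("sat_curve requires t > delta")
    return params.lam * -np.expm1(-params.phi * (t - params.delta))


def fit_sat_curve(times, accuracies) -> SATCurveFit:
    """Fit the exponential SAT curve to (time, accuracy) pairs by least squares.

    Minimizes the sum of squared residuals subject to lam in (0, 1], phi > 0
    and 0 <= delta < min(times).  Requires at least 4 strictly increasing time
    points (3 free parameters).  Degenerate inputs (no time dependence) and
    optimizer non-convergence are flagged on the returned :class:`SATCurveFit`
    rather than raised, so batch pipelines can inspect them.
    """
    times = _as_finite(times, "times")
    accuracies = _as_finite(accuracies, "accuracies")
    if times.ndim != 1 or times.shape != accuracies.shape:
        raise ValueError("times and accuracies must be 1-D and conformable")
    if times.size < 4:
        raise ValueError("need at least 4 (time, accuracy) pairs")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")

    t_min = float(times[0])
    eps = 1e-9
    lo = np.array([eps, eps, 0.0])
    hi = np.array([1.0, np.inf, max(t_min - eps * t_min, eps)])

    def resid(p):
        lam, phi, delta = p
        return lam * -np.expm1(-phi * (times - delta)) - accuracies

    span = float(times[-1] - times[0])
    x0 = np.array(
        [
            float(np.clip(np.max(accuracies), 0.05, 1.0)),
            1.0 / max(span, eps),
            0.5 * t_min,
        ]
    )
    x0 = np.clip(x0, lo, np.where(np.isfinite(hi), hi, x0 + 1.0))
    sol = least_squares(resid, x0, bounds=(lo, hi), method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14)

    params = SATCurveParams(
        lam=float(np.clip(sol.x[0], eps, 1.0)),
        phi=float(max(sol.x[1], eps)),
        delta=float(max(sol.x[2], 0.0)),
    )
    rss = float(np.sum(sol.fun**2))
    degenerate = float(np.ptp(accuracies)) < 1e-12
    converged = bool(sol.success) and not degenerate
    msg = "degenerate: accuracies do not vary with time" if degenerate else sol.message
    return SATCurveFit(params=params, rss=rss, converged=converged, message=msg)
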