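"""Sampler layer: log-joint oracle, DIC arithmetic, PSRF, MCMC contracts."""

import numpy as np
import pytest
from scipy import stats

from sathm import (
    Dataset,
    HyperParams,
    ItemParams,
    MCMCConfig,
    PersonParams,
    SimDesign,
    TestParams,
    dic,
    draw_persons,
    generate_dataset,
    log_joint,
    psrf,
    run_mcmc,
    simulate,
)
from sathm.models import rmm_prob, satm_prob, two_pl
from sathm.simulate import SimTruth


def _toy():
    """3 persons x 2 items with hand-set values (all supports interior)."""
    item = ItemParams(
        a=np.array([0.8, 1.4]),
        b=np.array([-0.3, 0.6]),
        beta=np.array([2.8, 3.2]),
        sigma=np.array([0.5, 0.9]),
        alpha=np.array([0.6, 1.1]),
    )
    test = TestParams(zeta=0.4)
    person = PersonParams(theta=np.array([-0.5, 0.2, 1.0]), tau=np.array([0.3, -0.4, 0.1]))
    hyper = HyperParams(sigma_theta_tau=0.35, mu_b=0.1, mu_beta=3.0, Sigma_I=np.array([[1.1, 0.2], [0.2, 0.3]]))
    dataset = Dataset(
        responses=np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]]),
        times=np.array([[12.0, 30.0], [8.0, 22.0], [15.0, 40.0]]),
    )
    return dataset, item, test, person, hyper


def _brute_force_log_joint(dataset, item, test, person, hyper, model):
    """Term-by-term reference using scipy.stats throughout."""
    total = 0.0
    z = np.empty_like(dataset.times)
    for i in range(dataset.n_persons):
        for j in range(dataset.n_items):
            t = dataset.times[i, j]
            mu_lt = item.beta[j] - person.tau[i]
            total += stats.norm.logpdf(np.log(t), mu_lt, item.sigma[j]) - np.log(t)
            z[i, j] = (np.log(t) - mu_lt) / item.sigma[j]
    for i in range(dataset.n_persons):
        for j in range(dataset.n_items):
            if model == "M0":
                p = two_pl(person.theta[i], item.a[j], item.b[j])
            elif model == "RMHM":
                p = rmm_prob(person.theta[i], item.a[j], item.b[j], item.alpha[j], z[i, j])
            else:
                p = satm_prob(person.theta[i], item.a[j], item.b[j], item.alpha[j], z[i, j], test.zeta)
            total += stats.bernoulli.logpmf(dataset.responses[i, j], p)
    rho = hyper.sigma_theta_tau
    cov_p = np.array([[1.0, rho], [rho, 1.0]])
    total += stats.multivariate_normal.logpdf(np.stack([person.theta, person.tau], axis=1), np.zeros(2), cov_p).sum()
    total += stats.multivariate_normal.logpdf(
        np.stack([item.b, item.beta], axis=1), [hyper.mu_b, hyper.mu_beta], hyper.Sigma_I
    ).sum()
    half = stats.truncnorm(0, np.inf, loc=0, scale=1)
    total += half.logpdf(item.a).sum()
    # prior stated on 1/sigma; Jacobian d(1/sigma)/d(sigma) = -1/sigma^2
    total += (half.logpdf(1.0 / item.sigma) - 2 * np.log(item.sigma)).sum()
    total += half.logpdf(item.alpha).sum()
    total += stats.norm.logpdf(test.zeta)
    total += stats.truncnorm(-1, 1).logpdf(rho)
    total += stats.invwishart.logpdf(hyper.Sigma_I, 2, np.eye(2))
    total += stats.norm.logpdf([hyper.mu_b, hyper.mu_beta], 0, np.sqrt(1000.0)).sum()
    return float(total)


class TestLogJoint:
    @pytest.mark.parametrize("model", ["SATHM", "RMHM", "M0"])
    def test_matches_term_by_term_oracle(self, model):
        dataset, item, test, person, hyper = _toy()
        expected = _brute_force_log_joint(dataset, item, test, person, hyper, model)
        assert log_joint(dataset, item, test, person, hyper, model) == pytest.approx(expected, abs=1e-8)

    def test_response_term_is_additive(self):
        dataset, item, test, person, hyper = _toy()
        full = log_joint(dataset, item, test, person, hyper, "SATHM")
        rt_only = log_joint(dataset, item, test, person, hyper, "SATHM", response_likelihood=False)
        resp = 0.0
        z = (np.log(dataset.times) - (item.beta[None, :] - person.tau[:, None])) / item.sigma[None, :]
        p = satm_prob(person.theta[:, None], item.a[None, :], item.b[None, :], item.alpha[None, :], z, test.zeta)
        resp = (dataset.responses * np.log(p) + (1 - dataset.responses) * np.log1p(-p)).sum()
        assert full - rt_only == pytest.approx(resp, abs=1e-8)

    def test_inflated_sigma_lowers_rt_likelihood(self):
        dataset, item, test, person, hyper = _toy()
        base = log_joint(dataset, item, test, person, hyper, "M0", response_likelihood=False)
        item_wide = ItemParams(a=item.a, b=item.b, beta=item.beta, sigma=item.sigma * 100, alpha=item.alpha)
        wide = log_joint(dataset, item_wide, test, person, hyper, "M0", response_likelihood=False)
        assert wide < base

    def test_out_of_support_returns_neg_inf(self):
        dataset, item, test, person, hyper = _toy()
        bad = HyperParams(sigma_theta_tau=0.0, mu_b=0.0, mu_beta=3.0, Sigma_I=np.eye(2))
        bad.sigma_theta_tau = 1.5  # bypass constructor check deliberately
        assert log_joint(dataset, item, test, person, bad, "SATHM") == -np.inf
        item.alpha = np.array([-0.5, 1.0])
        assert log_joint(dataset, item, test, person, hyper, "SATHM") == -np.inf
        assert np.isfinite(log_joint(dataset, item, test, person, hyper, "SATHM", truncate_alpha=False))


class TestDIC:
    def test_arithmetic(self):
        d_bar, p_d, val = dic([10.0, 12.0], 9.0)
        assert (d_bar, p_d, val) == (11.0, 2.0, 13.0)

    def test_degenerate_posterior(self):
        d_bar, p_d, val = dic([7.5, 7.5, 7.5], 7.5)
        assert p_d == 0.0 and val == 7.5

    def test_identity(self):
        rng = np.random.default_rng(0)
        draws = rng.normal(100, 5, size=50)
        at_mean = 95.0
        d_bar, p_d, val = dic(draws, at_mean)
        assert val == pytest.approx(2 * d_bar - at_mean, abs=1e-12)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            dic([], 1.0)
        with pytest.raises(ValueError):
            dic([1.0, np.inf], 1.0)


class TestPSRF:
    def test_identical_chains_near_one(self):
        rng = np.random.default_rng(1)
        one = rng.normal(size=(5000, 3))
        val = psrf(np.stack([one, one]))
        assert val == pytest.approx(1.0, abs=2.0 / 5000 + 1e-6)

    def test_same_distribution_small(self):
        rng = np.random.default_rng(2)
        chains = rng.normal(size=(2, 5000, 4))
        assert psrf(chains) < 1.05

    def test_separated_chains_large(self):
        rng = np.random.default_rng(3)
        chains = np.stack([rng.normal(0, 1, size=(500, 2)), rng.normal(10, 1, size=(500, 2))])
        assert psrf(chains) > 1.1 * 5

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            psrf(np.zeros((1, 100, 2)))


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            MCMCConfig(n_iter=100, burn_in=100)
        with pytest.raises(ValueError):
            MCMCConfig(thin=0)

    def test_retained_draw_bookkeeping(self):
        _, data = simulate(SimDesign(n_persons=10, n_items=3, seed=0))
        cfg = MCMCConfig(n_iter=52, burn_in=50, n_chains=2, thin=2, seed=1)
        res = run_mcmc(data, "SATHM", cfg)
        assert res.chains["zeta"].shape == (2, 1)  # ceil(2/2) = 1 per chain
        cfg3 = MCMCConfig(n_iter=57, burn_in=50, n_chains=2, thin=3, seed=1)
        res3 = run_mcmc(data, "SATHM", cfg3)
        assert res3.chains["zeta"].shape == (2, 3)  # ceil(7/3)


@pytest.fixture(scope="module")
def small_fit():
    _, data = simulate(SimDesign(n_persons=60, n_items=8, seed=21))
    cfg = MCMCConfig(n_iter=600, burn_in=300, n_chains=2, thin=2, seed=5)
    return run_mcmc(data, "SATHM", cfg), data, cfg


class TestRunMCMC:
    def test_reproducible(self, small_fit):
        res, data, cfg = small_fit
        res2 = run_mcmc(data, "SATHM", cfg)
        for key in ("theta", "a", "sigma", "zeta", "Sigma_I"):
            np.testing.assert_array_equal(res.chains[key], res2.chains[key])

    def test_draws_respect_supports(self, small_fit):
        res, _, _ = small_fit
        assert np.all(res.chains["a"] > 0)
        assert np.all(res.chains["sigma"] > 0)
        assert np.all(res.chains["alpha"] > 0)  # truncated prior by default
        rho = res.chains["sigma_theta_tau"]
        assert np.all((rho > -1) & (rho < 1))
        sig = res.chains["Sigma_I"].reshape(-1, 2, 2)
        dets = sig[:, 0, 0] * sig[:, 1, 1] - sig[:, 0, 1] ** 2
        assert np.all(dets > 0) and np.all(sig[:, 0, 0] > 0)

    def test_summary_interval_contains_mean(self, small_fit):
        res, _, _ = small_fit
        s = res.summary
        assert np.all(s["ci_lower"] <= s["ci_upper"])
        assert np.all((s["mean"] >= s["ci_lower"] - 1e-9) & (s["mean"] <= s["ci_upper"] + 1e-9))

    def test_dic_identity_holds_exactly(self, small_fit):
        res, _, _ = small_fit
        for tag in ("joint", "response"):
            d = res.deviance[tag]
            assert d["dic"] == d["dbar"] + d["p_d"]
            assert d["p_d"] == d["dbar"] - d["deviance_at_mean"]

    def test_unknown_model_rejected(self, small_fit):
        _, data, cfg = small_fit
        with pytest.raises(ValueError):
            run_mcmc(data, "3PL", cfg)


class TestRTOnlyOracle:
    def test_beta_contrasts_match_normal_theory(self):
        # designed instance: equal moderate residual SDs, so the normal-theory
        # column-mean estimates of the time-intensity contrasts are the truth
        # the hierarchical posterior must reproduce (shrinkage is negligible)
        n, m = 150, 6
        design = SimDesign(n_persons=n, n_items=m, seed=31)
        rng = np.random.default_rng(31)
        item = ItemParams(
            a=np.full(m, 1.0),
            b=np.zeros(m),
            beta=np.array([2.4, 2.8, 3.0, 3.1, 3.3, 3.8]),
            sigma=np.full(m, 0.5),
            alpha=np.full(m, 0.7),
        )
        person = draw_persons(design, rng)
        hyper = HyperParams(0.5, 0.0, 3.0, np.array([[1.0, 0.25], [0.25, 0.25]]))
        truth = SimTruth(item=item, test=TestParams(zeta=0.5), person=person, hyper=hyper, design=design)
        data = generate_dataset(truth, rng)

        cfg = MCMCConfig(n_iter=3000, burn_in=1000, n_chains=2, thin=2, seed=7)
        res = run_mcmc(data, "SATHM", cfg, response_likelihood=False)
        bhat = res.posterior_means["beta"]
        col = np.log(data.times).mean(axis=0)
        np.testing.assert_allclose(bhat - bhat.mean(), col - col.mean(), atol=0.05)
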