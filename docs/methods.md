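# Methods

## The models

For person *i* (of N) and item *j* (of m) we observe a binary response
U<sub>ij</sub> and a response time T<sub>ij</sub> in seconds.

**Response-time submodel** (shared by all three models): a lognormal model
linked by latent speed,

    ln T_ij ~ N(beta_j - tau_i, sigma_j^2)

with item time intensity beta_j (log-seconds), person speed tau_i, and item
residual SD sigma_j. The standardized residual log time

    Z_ij = (ln T_ij - (beta_j - tau_i)) / sigma_j

measures how much longer than expected this particular response took; it is
the driver of the speed-accuracy tradeoff term.

**Response submodels.** The asymptotic ("time-unlimited") accuracy is the
two-parameter logistic

    lambda_ij = exp(a_j theta_i - b_j) / (1 + exp(a_j theta_i - b_j)).

Note the linear predictor is `a*theta - b`, not `a*(theta - b)`; both
conventions exist in IRT and they are not interchangeable.

* **M0** (traditional hierarchical model): P(U=1) = lambda. Responses and
  times are linked only through the person- and item-level covariances.
* **RMHM** (response moderation): P(U=1) = logistic(a theta - b + alpha_j Z).
  The residual time shifts the linear predictor, so sufficiently slow
  responding drives the probability to 1 for any ability.
* **SATHM** (speed-accuracy tradeoff): the asymptote is attenuated by an
  exponential approach-to-asymptote time factor,

      P(U=1) = lambda_ij * (1 - exp(-exp(alpha_j Z_ij + zeta)))

  with item slope alpha_j and a test-level intercept zeta. As the residual
  time grows the factor rises to 1 and the model reduces to the 2PL; accuracy
  can never exceed the ability-determined asymptote, which is the substantive
  difference from RMHM. The double exponential keeps the implied effective
  processing time positive. This form is the hierarchical reconstruction of
  the classic experimental SAT curve d(t) = lam*(1 - exp(-phi*(t - delta))),
  which `sathm.fit_sat_curve` fits to (time, accuracy) pairs by bounded
  least squares.

**Hierarchical level.** (theta_i, tau_i) are bivariate normal with means 0
and variances 1 — the identification restrictions, enforced by construction,
which make the covariance sigma_theta_tau a correlation. (b_j, beta_j) are
bivariate normal with mean (mu_b, mu_beta) and covariance Sigma_I.

## Priors and estimation

Priors: a_j, 1/sigma_j, alpha_j ~ N(0,1) truncated to (0, inf); zeta ~
N(0,1); sigma_theta_tau ~ N(0,1) truncated to (-1, 1); Sigma_I ~
inverse-Wishart(I_2, 2); mu_b, mu_beta ~ N(0, 1000). Two notes on choices
that were genuinely open:

* The vague N(0, 1000) hyperpriors on (mu_b, mu_beta) read a precision-style
  notation as a variance-1000 normal; with hierarchically drawn (b, beta)
  this is the only structure under which the item-level means and covariance
  are themselves estimated, which is what the model reports.
* The positive truncation of alpha_j forbids negative residual-time effects.
  Empirical data can want them (hard items answered slowly and still wrongly),
  so `MCMCConfig.truncate_alpha=False` switches to an untruncated N(0,1).
  The truncated prior is the default.

**Sampler.** Metropolis-within-Gibbs. Conjugate draws where they exist —
(mu_b, mu_beta) given items (bivariate normal) and Sigma_I given items
(inverse-Wishart, drawn by a 2x2 Bartlett construction) — and adaptive
random-walk Metropolis everywhere else, vectorized across persons or items
(each coordinate is its own accept/reject). sigma_j uses a multiplicative
(log-scale) walk with the Hastings correction. Proposal scales adapt every
50 iterations toward an acceptance rate of 0.44 (the standard scalar-target)
with a decaying step, and are frozen when burn-in ends, so the post-burn-in
kernel is a fixed Markov kernel. Initialization is deterministic
(method-of-moments: standardized scores and log-time means), so a run is a
pure function of (dataset, model, config); chains differ only through RNG
streams spawned from `config.seed`.

Default protocol: 30000 iterations, 10000 burn-in, 2 chains, thinning 2.
Convergence is monitored by the Brooks–Gelman multivariate PSRF computed over
the item-, test- and hyper-level block (person parameters are excluded to
keep the covariance well conditioned); a fit with MPSRF >= 1.1 is returned
flagged, never silently dropped.

**DIC.** DIC = D-bar + pD with D-bar the posterior mean deviance and pD =
D-bar - D(posterior means of all parameters, persons included). The deviance
convention matters in a joint model: the default uses the joint conditional
likelihood of responses *and* response times, which is the only convention
under which M0 / RMHM / SATHM are comparable (they share the RT submodel);
the response-only deviance is computed and reported alongside, and the
convention is recorded in the result metadata.

## Synthetic-data generator

`SimDesign` defaults are the study conditions: N in {500, 1000}, m in
{30, 60}; persons bivariate normal with correlation 0.5; a_j, 1/sigma_j,
alpha_j standard normal truncated positive (inverse-CDF sampling, so draws
are reproducible across platforms); zeta ~ N(0,1) per dataset; (b_j, beta_j)
~ MVN((0, 3), [[1, .25], [.25, .25]]) with beta in log-seconds. Data are
generated by composing the three model layers with the *true* parameters
(forced by the model's definition: Z is defined through the generating
values). Complete data only — the missingness mask exists for empirical
input support, not for generation.

Two numerical notes. Simulated log times are clipped at +/-700 before
exponentiation: the half-normal prior on 1/sigma puts no lower bound on the
precision, so a rare item draw has sigma in the hundreds and exp(lnT) would
overflow double precision; the clip binds only where "seconds" has long lost
meaning. Second, the same heavy tail means an occasional item carries almost
no response-time information — real timed-test data do not behave like this,
so recovery summaries for beta and tau from this generator are somewhat
pessimistic relative to data with residual SDs near 1.

What the generator does not emulate: test-level time limits (censoring /
not-reached items), item-position effects, between-person tradeoff
heterogeneity, and non-lognormal RT shapes. Passing recovery tests therefore
show the estimator is correct under the model, not that the model fits any
particular empirical test.

## Recovery scoring

MSE and bias pool signed errors of posterior means over replications and
over the family's parameters: denominators R*m for item families, R*N for
person families, R*1 for the test-level zeta. The residual-spread family is
scored on the precision scale (1/sigma) — the scale the parameter is drawn
and priored on — because the sigma scale is heavy-tailed and a single
near-zero precision draw would dominate the squared error. The estimate used
is the posterior mean of 1/sigma. Non-converged replications are counted and
included; a converged-only table is reported alongside.

Reduced study sizes are used throughout the test suite and the acceptance
script: 5 replications (3 at m=60) with 6000-iteration / 2000-burn-in chains
at the (500, 30) and (500, 60) cells, chosen so a study completes in minutes
on one CPU while leaving the per-replication posterior-mean error well below
the parameter-level error it is scoring. At these chain lengths MPSRF
typically sits in 1.3–1.8 — above the 1.1 convergence bar the full protocol
reaches — but the posterior means, which are all recovery scoring uses, agree
with the 30000-iteration protocol to ~0.01 on every family, so the reduced
studies measure the same quantities with more Monte-Carlo noise.

## Known limitations

* MSE of ability estimates is governed by the attenuated response
  information: with zeta ~ N(0,1) the time factor averages well below 1, so
  theta recovery is intrinsically worse than for a plain 2PL with the same
  items, and datasets with a strongly negative zeta draw carry very little
  ability information at all. MSE(theta) from this generator is
  correspondingly dataset-dependent.
* The sampler is a random-walk scheme; posterior geometry with very weak
  attenuation (zeta large) makes alpha_j and zeta only weakly identified,
  and those blocks then mix slowly.
* DIC is the only model-selection criterion provided; no Bayes factors,
  WAIC/LOO, or posterior predictive checks.
* Person-level tradeoff heterogeneity (person-specific alpha) and
  curvilinear residual-time effects are out of scope.
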