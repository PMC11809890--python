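# Methods

## The problem

Adequate antenatal care (at least four contacts, the WHO minimum) and
delivery at a health facility are two binary outcomes recorded for the same
woman, and they are strongly dependent: a woman who attends antenatal care
is far more likely to deliver in a facility.  Survey data of this kind is
also clustered — women are sampled within administrative zones, and zones
differ systematically.  Analysing the two outcomes separately discards the
dependence; ignoring the clustering understates uncertainty and conflates
within- and between-zone effects.  `bivmlogit` fits both features jointly:
a bivariate logistic model whose association is a cell odds ratio, with a
zone-level random intercept, estimated by Laplace-approximated maximum
likelihood.

## The model

For woman *i* in zone *c*, let `y1` indicate adequate antenatal care and
`y2` facility delivery.  Conditional on the zonal effect `u_c`,

    logit P(y1 = 1 | u_c) = x1' beta1 + u_c
    logit P(y2 = 1 | u_c) = x2' beta2 + u_c

and the joint distribution of the pair is the unique 2x2 table with those
margins and cell odds ratio

    psi = p11 * p00 / (p10 * p01) = exp(alpha),

the Plackett (global odds-ratio) coupling.  The outcome pair is one
four-category multinomial draw, so a unit's log-likelihood is the log of
the cell selected by its observed pair.  `psi = 1` is conditional
independence; the model reduces exactly to two separate logistic
regressions when `alpha = 0` and `sigma = 0` (a property the test suite
exploits as an oracle).

Random-effect structures:

* **shared** (default): one zonal intercept enters both predictors with a
  single scale `sigma`.  This matches reporting a *single* ICC for both
  outcomes and is the most parsimonious way to induce within-zone
  correlation in both services at once.
* **independent**: separate intercepts per outcome, `(sigma1, sigma2)`.
* **correlated**: bivariate normal intercepts `(sigma1, sigma2, rho)`.

The association is specified on the *conditional* (within-zone) scale:
cells are built from the conditional margins.  The marginal (population-
averaged) odds ratio between the outcomes is therefore larger than
`exp(alpha)` whenever `sigma > 0`, because the shared intercept adds
association when the zones are mixed — the generator's crude OR of ~15 at
`psi = 6.38`, `sigma^2 = 2.38` is this effect, not a bug.

### Inversion of the odds-ratio parameterization

Given margins `(p1, p2)` and `psi`, `p11` solves a quadratic; we take the
"-" root of `a = 1 + (p1 + p2)(psi - 1)`, which is the one inside the
Frechet bounds `max(0, p1 + p2 - 1) <= p11 <= min(p1, p2)`.  Within
`|psi - 1| < 1e-6` the quadratic formula cancels catastrophically, so a
second-order series around independence is used instead.  Both branches
are finished with two Newton polish steps on the defining equation
`p11 p00 - psi p10 p01 = 0` (whose derivative `p00 + p11 + psi(p10+p01)`
is strictly positive on the Frechet interval), which lands either branch
on the root to machine precision and makes the branch switch continuous to
well below 1e-12.  Round-trip accuracy (`cell_odds_ratio` after
`plackett_cells`) is ~1e-12 relative over `psi` in [0.01, 100].

### Marginal likelihood

The zonal effects are integrated out per cluster.  The integrand's mode is
found by a damped, vectorized Newton iteration across all clusters at once
(analytic gradient through the implicit derivatives of the Plackett cell;
curvature by central-differencing that gradient — the prior's Hessian is
exact since it is linear in `u`).  The Laplace value is

    l(u_hat) + (d/2) log 2pi - (1/2) log det(-H(u_hat)).

`sigma = 0` short-circuits to the fixed-effect likelihood (the integral is
degenerate, no approximation).  Adaptive Gauss–Hermite quadrature with
nodes recentred at the mode and rescaled by the curvature is provided as a
cross-check; one node reproduces Laplace identically, and 15 vs 25 nodes
agree to ~1e-9 on test fixtures.  For two-dimensional structures the AGQ
grid is a tensor product through the Cholesky factor of the inverse
curvature.

### Outer optimization and inference

L-BFGS-B over `(beta1, beta2, alpha, log sigma [, atanh rho])` with
finite-difference gradients; the mode search warm-starts from the previous
evaluation.  Initialization: separate IRLS logistic fits for the betas,
the crude 2x2 log odds ratio (Haldane-corrected, clipped to [-4, 4]) for
`alpha`, and an empirical-logit between-cluster moment guess for `sigma`
(0.5 if degenerate).  Convergence: `ftol 1e-11`, `gtol 1e-6`; the inner
Newton runs to gradient 1e-10 with at most 100 iterations and per-cluster
step halving.  `log sigma` is bounded in [-10, 3]; estimates at the lower
bound mean the variance has collapsed to ~0.

Standard errors come from the inverse of a central finite-difference
Hessian of the marginal log-likelihood at the optimum; if that matrix is
not positive definite the SEs are flagged unavailable and the point
estimates still returned.  Inference is Wald (z = beta/SE), significance
at 0.05, no multiplicity correction.  Derived quantities use the delta
method implicitly through the monotone transforms (`AOR = exp(beta)`,
`sigma^2 = exp(2 log sigma)`); CI endpoints are transformed endpoints.

### ICC and information criteria

The latent-threshold ICC is `sigma^2 / (sigma^2 + pi^2/3)`: the level-1
residual of the latent-logistic formulation has variance pi^2/3 = 3.2898,
conventionally quoted as 3.29 in survey reports (computations use the
exact constant; serialized results carry the display value).  `AIC = -2l +
2p`; `BIC = -2l + p ln(n)` with `n` = the number of *clusters* by default
(the convention of mixed-model software estimating by Laplace; a flag
switches to units).  The model ladder fits null, individual-covariate,
community-covariate, and full models and flags the AIC/BIC minimizers.

## The synthetic world

The survey microdata is access-restricted, so the generator is the test
bed and ground truth.  Defaults state the emulated survey: 68 zones with
negative-binomial sizes (mean 57.7, shape 8, floor 5; total ~3,926 women),
covariate marginals equal to the published weighted frequencies (age 7
levels, education 4, wealth 3, media 2, residence 2; residence drawn per
zone), true coefficients a sparse subset of the published adjusted model
(education, wealth, media, residence), `log psi = ln 6.381`, shared
`sigma^2 = 2.38` (inverting a null-model ICC of 0.42), weights 1.0 (a
lognormal jitter rule exercises the weighted descriptive layer).

Two deliberate design choices:

* **Intercepts are calibrated, not copied.**  The published intercepts
  condition on the reference cells of a ~30-term model; applied to the
  sparse subset they would drive the outcome margins far from the
  published 43.0% / 52.5%.  The defaults (-0.723, -0.098) were obtained
  once by Monte-Carlo root finding (2e6 draws) so the population-average
  margins equal the published ones.
* **The ladder-attenuation world adds region.**  With the sparse default,
  a fitted full-model ICC can *exceed* the null ICC: unit-level covariates
  rescale the latent variance (the level-1 variance is pinned at pi^2/3),
  and the small residence effect cannot offset it.  That is a real
  property of latent-scale ICCs, not an artifact.  The published ladder's
  0.42 -> 0.29 attenuation arises because region explains most of the
  zonal variation; `region_informative_config()` reproduces that world
  from printed values only — region (11 levels, published marginals and
  adjusted coefficients) and residence as community covariates, residual
  zonal variance 1.3437 inverting the published final-model ICC of 0.29.
  Under it the null ICC exceeds the full ICC in 10/10 test seeds.

What the generator does **not** emulate: the two-stage enumeration-area /
household sampling design, covariate-covariate correlation (marginals
only), item nonresponse patterns, and the true zone-size distribution
(unpublished; the negative binomial is a stand-in).  A green recovery test
therefore establishes that the estimator is consistent and calibrated
*under the model*, not that the published coefficient table is
reproducible — that would require the restricted microdata.

## Numerical and coding conventions

* Outcomes are 1 = at least four antenatal contacts, 1 = facility
  delivery; any other coding is mapped by the caller.
* Categorical encoding is explicit: declared level order, declared
  reference level, `k - 1` indicators, intercept first.  Column order is
  configuration, never inferred from data order, so coefficient tables
  are reproducible.
* Rows missing an outcome or cluster id are dropped at load (counted);
  missing covariate cells become an explicit `"missing"` level retained in
  descriptives and excluded from design encoding.
* Descriptive tables are always weighted; model fitting is unweighted by
  default with a pseudo-likelihood flag (weights multiply unit log-lik
  terms; the provenance of the published model table w.r.t. weights is
  unstated).
* Chi-square tests act on the weighted counts directly — design-naive, no
  Rao–Scott correction — matching the reproduced tables; a limitation, not
  a recommendation.
* The 2x2 odds-ratio CI is the Woolf log interval, which reproduces the
  published interval from the published cells; zero cells raise unless the
  Haldane–Anscombe +0.5 correction is requested (off by default).
* The association `alpha` is intercept-only.  A covariate-dependent
  `psi(x)` (the Dale-model generalization) is a known limitation; the
  reproduced analysis reports a single association OR.
* Every stochastic routine takes an explicit seed; replicate seeds are
  spawned from one root generator.

## Known limitations

* Laplace is a first-order approximation; with very small clusters and
  large `sigma^2` it is biased relative to high-order AGQ (use
  `agq_marginal_loglik` to check a fitted model).
* No survey-design variance estimation (linearization or replicate
  weights), no three-level nesting, no spatial zone effects, no Bayesian
  or bootstrap inference.
* The weighted pseudo-likelihood does not rescale weights within
  clusters; cluster-level weight informativity is not addressed.
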