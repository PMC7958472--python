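# Methods

## The model

`poolprof` addresses a deconvolution problem in transcriptomics: a tissue is
a mixture of `T` latent cell populations (regulatory states), but expression
is measured only as the cumulative signal of small pools of `n_i` randomly
drawn cells — "stochastic profiling". Per gene `g`, a single cell from
population `h` expresses

- `X ~ LN(mu_h^(g), sigma^2)` — **LN-LN** family (shared log-sd, hence a
  shared coefficient of variation `sqrt(exp(sigma^2) - 1)` across
  populations),
- `X ~ LN(mu_h^(g), sigma_h^2)` — **rLN-LN** family (population-specific
  spread),
- or, for the last population of the **EXP-LN** family,
  `X ~ Exp(lambda^(g))` — a one-parameter choice whose support includes
  zero, for genes with many zero or near-zero measurements.

A pool's observation is `Y_i = X_1 + ... + X_{n_i}`. Conditioning on the
latent *composition* `l = (l_1, ..., l_T)` (how many cells of each
population the pool holds, multinomial with cell fractions `p`), the pooled
density is the finite mixture

    f_{n_i}(y) = sum_l  multinomial(l; n_i, p) * f_l(y),

over all `C(n_i + T - 1, T - 1)` compositions. The log-likelihood sums
`log f_{n_i}(y_i^(g))` over samples and genes (genes are modelled as
independent; log-sds are shared across genes, log-means and rates are
gene-specific).

### Convolution building blocks

Sums of lognormals have no closed-form density. A composition's lognormal
cells are collapsed into a single lognormal whose mean and variance equal
those of the sum *exactly* (Fenton–Wilkinson moment matching):
`sigma_B^2 = log(Delta/Gamma^2 + 1)`, `mu_B = log(Gamma) - sigma_B^2/2`
where `Gamma`/`Delta` are the summed means/variances. Moment matching is
associative, so collapsing all summands at once equals pairwise combining;
each composition therefore costs one closed-form density evaluation
(LN families) or one numeric convolution (EXP-LN). The approximation is
accurate for the narrow log-sds typical here (tested: Kolmogorov distance
< 0.02 to the empirical distribution of 10 i.i.d. LN(0, 0.2^2) sums).

The exponential cells of an EXP-LN composition sum to an Erlang
distribution (gamma with integer shape). Its convolution with the collapsed
lognormal is an integral over `[0, y]` with a smooth, single-peaked
integrand. Two implementations exist deliberately:

- the scalar `exp_lognormal_convolution_pdf` uses adaptive Gauss–Kronrod
  quadrature (`scipy.integrate.quad`, abs. tol 1e-10, rel. 1e-8) and is the
  reference;
- the vectorized likelihood path uses a fixed 96-node Gauss–Legendre rule,
  which agrees with the reference to ~1e-6 relative while being orders of
  magnitude faster over a vector of observations. Tests cross-check the two
  routes.

Densities are accumulated in log space; each log-likelihood term is floored
at -745 (the smallest normal double's log) so the objective stays finite
where a density underflows.

## Estimation

The likelihood surface is multimodal. The fit alternates a randomized grid
search (cheap, global) with Nelder–Mead restarts from the best grid points
(costly, local): 500 uniform draws per round, top 5 carried to Nelder–Mead,
then the search ranges contract to the bounding box of the local maxima
padded by 20%. Three rounds form one loop; five loops by default, or until
the between-loop improvement falls below 5e-5.

Optimization is unconstrained: probabilities pass through a
multinomial-logit transform with the last population as reference (any
finite vector back-transforms onto the simplex; the all-zero point maps to
the uniform vector), `sigma` and `lambda` are log-transformed, and
population labels are fixed by ordering the lognormal populations by the
first gene's log-means (`mu_1^(1) > mu_2^(1) > ...`, ties broken by later
genes). Without the ordering, label permutations would create spurious
symmetric modes.

Initial search ranges adapt to the data: `mu` coordinates span
`[min, max]` of `log(y_i / n_i)` widened by ±2; `log sigma` spans
`[log 0.01, log 2]`; simplex coordinates span `[-3, 3]`; `log lambda` is
centred on the reciprocal per-cell mean. One seed controls the whole fit.

For many genes, `staged_fit` first fits small gene subsets and seeds the
joint fit with the assembled estimates, which tames the growing number of
modes (at minimum `T(m+1)` parameters).

Approximate marginal 95% confidence intervals: the Hessian of the negative
log-likelihood at the transformed optimum is computed by central finite
differences (relative step 1e-4); with `d_i` the i-th diagonal element of
its inverse, bounds `z_i ± 1.96 sqrt(d_i)` are back-transformed
componentwise. A non-positive-definite Hessian yields explicit `None`
bounds with a warning rather than fabricated intervals. Model order is
chosen by BIC, `-2 loglik + log(k) dim(theta)`, smallest wins.

## Synthetic data

The generator emulates the idealized measurement process: cell labels drawn
multinomially per pool (no fixed quotas), per-gene values from the labelled
population, pools summed, labels shared across genes so the latent
composition is common to all genes and recorded as ground truth. Default
study conditions mirror the regimes used throughout the tests: a
two-population LN-LN model with `p = 0.62, mu = (0.47, -0.87),
sigma = 0.03` for dense, well-identified data, and
`p = 0.2, mu = (2, 0), sigma = 0.2` for the sparse minority-population
regime; mixed pool-size presets `{1,2,5,10}` and `{10,15,20,50}` cycle
evenly over the samples. `perturb_pool_sizes` draws Poisson(n_i) per
component (zeros floored at one) to emulate uncertain cell counts.

No technical measurement noise is simulated — deliberately, so tests
isolate the estimator's statistical behaviour. Passing tests therefore
demonstrate correctness of the inference machinery under the model, not
robustness to the noise, dropout or gene–gene correlation of real
single-cell data.

## Comparing inferred populations

The overlap coefficient `OVL(f, g) = int min{f, g}` is computed exactly on
the log scale (OVL is invariant under strictly monotone axis
transformations): `2 Phi(-|dmu| / (2 sigma))` for equal log-sds, otherwise
via the two roots of the quadratic log-density difference with interval
masses from the normal CDF.

Whether an OVL is small enough to call two fitted populations different
depends on the effective data behind each estimate,
`round(p_hat * total cells)`. The sampling-based test simulates the null:
parameters averaged, `N = 1000` pairs of single-cell datasets of the two
effective sizes drawn and refitted (closed-form lognormal MLE: mean and
ddof=0 sd of the logs), and the original OVL compared to the empirical 5%
quantile (lower order statistic `ceil(0.05 N)`). Fewer effective cells
widen the null distribution downward, making rejection properly harder.

## Composition prediction

Plug-in (empirical-Bayes-style) two-step inference: fit `theta_hat`, then
evaluate `P(l | y) ∝ multinomial(l; n, p_hat) * prod_g f_l(y^(g))` over the
full composition support, normalized by log-sum-exp. Reported summaries:
the posterior argmax (MLE), the posterior mean count vector, and the
smallest credible set reaching 0.95 mass (compositions added in descending
probability, ties broken by the smaller first-population count).
Uncertainty in `theta_hat` is not propagated — the hypothetical full
posterior over parameters and compositions is out of scope.

## Problem sizes in the shipped studies

The test suite and acceptance script run reduced replicate counts chosen as
desk-scale versions of full simulation studies: 5 replicate fits of the
`k = 1000, n = 10` recovery regime; 3 seeds of the `k = 100, n = 5`
composition study; 100 datasets per pool size `n in {1, 5, 10}` at `k = 50`
for the pool-size sweep (these fits use a reduced search — 2 loops, 150
grid points, top 2 — which the well-separated regime tolerates without
visible bias); 200 replicates for the size of the overlap test. Monte-Carlo
oracles use 1e5–1e6 draws.

## Known limitations

- The Fenton–Wilkinson approximation degrades for large log-sds
  (sigma >~ 1) and very skewed compositions; the models here target
  sigma ~ 0.01–0.5 where it is excellent.
- Likelihood cost grows with `C(n + T - 1, T - 1)`; pools beyond ~50 cells
  or `T > 3` become expensive and estimates are known to widen with pool
  size anyway.
- Zeros are outside the lognormal support: LN-only families reject them
  with advice (small offset, or the EXP-LN family) instead of silently
  shifting the data.
- Gene independence within a sample is assumed; correlated genes will make
  joint fits overconfident.
- When sigma is very small relative to the log-mean separation, the pooled
  density of homogeneous n-cell pools is a train of narrow spikes at
  `l*exp(mu_1) + (n-l)*exp(mu_2)`. A parameter combination that shifts every
  composition by one cell (adjusting `p` accordingly) reproduces almost the
  same spike train, so on occasional datasets the *global* maximum-likelihood
  estimate lands on such an aliased mode far from the generating values, and
  its Hessian-based intervals — narrow and centred on that mode — exclude
  the truth. This is a property of the likelihood in the near-degenerate
  regime, not of the optimizer: fits seeded at the generating values move to
  the aliased mode because it genuinely attains higher likelihood. Mixed
  pool sizes break the degeneracy.
- No multiple-testing correction is applied when the overlap test is run
  across many genes.
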