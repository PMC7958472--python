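# poolprof

Stochastic profiling of gene expression: maximum-likelihood inference of
single-cell population structure from measurements of **small random pools
of cells**.

Tissues are often mixtures of latent cell populations (regulatory states,
tumour subclones) with distinct expression distributions. Single-cell
measurements resolve this directly but are costly and noisy; bulk
measurements average it away. Stochastic profiling takes the middle road:
measure the cumulative expression `Y_i = X_1 + ... + X_{n_i}` of pools of a
few cells, and *demix statistically*. `poolprof` is for experimentalists and
statisticians who have such pooled measurements (or want to plan a pooling
design) and need mixture fractions, per-population expression
distributions, significance calls for differences between groups, and
per-pool composition predictions — all without signature matrices or other
prior knowledge of the populations.

## Model

Each cell belongs to population `h ∈ {1..T}` with probability `p_h`.
Per gene, single-cell expression is lognormal `LN(μ_h, σ²)` (families:
**LN-LN** shared σ, **rLN-LN** per-population σ_h, **EXP-LN** with one
exponential population `Exp(λ)` for zero-inflated genes). Conditioning on a
pool's latent composition `ℓ = (ℓ_1..ℓ_T)`, `Σℓ_h = n_i`, the pooled
density is a combinatorial mixture over all compositions,

    f_{n_i}(y | θ, p) = Σ_ℓ  ( n_i choose ℓ ) p_1^{ℓ_1} ··· p_T^{ℓ_T} · f_ℓ(y | θ),

where `f_ℓ` is the convolution of the per-population sums: sums of
lognormals are collapsed by Fenton–Wilkinson moment matching (one lognormal
carrying the sum's exact mean and variance), sums of exponentials are
Erlang, and the Erlang–lognormal cross convolution is integrated
numerically. Parameters maximize `ℓ(θ) = Σ_g Σ_i log f_{n_i}(y_i^{(g)})`
via randomized grid search alternated with Nelder–Mead in an unconstrained
parameterization; Hessian-based 95% CIs and BIC-based choice of `T` come
with the fit. Downstream: the overlap coefficient
`OVL = ∫ min{f, g}` with a sampling-based test of population equality, and
plug-in posteriors `P(ℓ | y)` over each pool's composition.

## Worked example

Simulate 1000 ten-cell pools from a two-population LN-LN model
(62% of cells in a high population), then re-infer the parameters:

```python
import poolprof as pp

spec   = pp.ModelSpec("LN-LN", T=2)
truth  = pp.ParameterSet(p=[0.62, 0.38], mu=[[0.47], [-0.87]], sigma=[0.03])
config = pp.SimulationConfig(spec=spec, theta=truth,
                             pool_sizes=pp.make_pool_sizes(1000, 10), rng_seed=1)
data   = pp.simulate_pooled_dataset(config)

fit = pp.fit_maximum_likelihood(data, spec, loops=3, until_convergence=True,
                                rng_seed=2)
```

This prints (via the snippet in the repo, seconds of runtime):

```
p1    = 0.6176   CI (0.608, 0.6271)
mu1   = 0.4695   CI (0.4683, 0.4708)
mu2   = -0.8675  CI (-0.8739, -0.8612)
sigma = 0.0293   CI (0.028, 0.0306)
loglik = -1124.96, BIC = 2277.54
```

All four 95% confidence intervals cover the true values — the mixture was
demixed from sums of ten cells without ever observing a single cell. The
per-pool composition posterior then recovers how many high-population cells
each individual pool contained:

```python
post = pp.composition_posterior(data.y[0], 10, fit.theta_hat, spec)
# pool 1 truth: [7 3]   posterior MLE: [7 3]   P = 1.0
```

and the overlap coefficient quantifies similarity of two inferred
populations, e.g. `pp.ovl(LN(2.10, 0.19²), LN(2.03, 0.20²)) = 0.8561` —
86% overlap, whose significance `pp.overlap_null_test` judges against the
effective number of cells behind each estimate.

The same workflow is available from the shell:

```bash
poolprof simulate --model LN-LN --T 2 --p 0.62,0.38 --mu 0.47,-0.87 \
    --sigma 0.03 --n 10 --k 1000 --seed 1 --out sim
poolprof fit sim.csv --model LN-LN --T 2 --n 10 --seed 2 --out fit.json
poolprof predict-composition sim.csv --report fit.json --n 10 --out pred
```

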