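"""Maximum-likelihood fitting of the pooled mixture models.

The log-likelihood surface is multimodal, so a single local optimization is
not reliable.  The search alternates a randomized grid search (cheap, global)
with Nelder--Mead restarts from the best grid points (costly, local),
contracting the search ranges around the local maxima found.  Three such
rounds form one loop; the whole procedure is repeated (five loops by
default, or until the between-loop improvement drops below 5e-5).

Optimization runs in an unconstrained space: population probabilities are
mapped through a multinomial-logit transform (so they still sum to one after
back-transformation), sigma and lambda are log-transformed, and population
labels are fixed by ordering the lognormal populations by the first gene's
log-means, mu_1^(1) > mu_2^(1) > ...

Approximate 95% confidence intervals come from the numerically computed
Hessian of the negative log-likelihood at the transformed optimum:
theta_i +/- 1.96 sqrt(d_i) with d_i the i-th diagonal element of the inverse
Hessian, back-transformed componentwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .model import ModelSpec, ParameterSet, PooledDataset, log_likelihood

#: stop the outer loops once the likelihood improves by less than this
CONVERGENCE_TOL = 5e-5


# ---------------------------------------------------------------------------
# parameter transforms


def _softmax_probs(q: np.ndarray, T: int) -> np.ndarray:
    """Multinomial-logit back-transform with the last population as reference;
    the all-zero point maps to the uniform simplex vector."""
    z = np.concatenate([q, [0.0]])
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def param_names(spec: ModelSpec) -> list[str]:
    """Names of the free (transformed) parameters, in vector order."""
    names = [f"p_{h + 1}" for h in range(spec.T - 1)]
    for h in range(spec.n_lognormal_pops):
        for g in range(spec.m):
            names.append(f"mu_{h + 1}_g{g + 1}" if spec.m > 1 else f"mu_{h + 1}")
    if spec.n_sigma == 1:
        names.append("sigma")
    else:
        names += [f"sigma_{h + 1}" for h in range(spec.n_sigma)]
    if spec.family == "EXP-LN":
        names += [f"lambda_g{g + 1}" if spec.m > 1 else "lambda" for g in range(spec.m)]
    return names


def transform_params(theta: ParameterSet, spec: ModelSpec) -> np.ndarray:
    """Map a valid ParameterSet to the unconstrained optimization space."""
    theta.validate(spec)
    if np.any(theta.p <= 0) or np.any(theta.p >= 1):
        if spec.T > 1:
            raise ValueError("boundary probabilities (0 or 1) cannot be transformed")
    q = np.log(theta.p[:-1] / theta.p[-1]) if spec.T > 1 else np.empty(0)
    parts = [q, theta.mu.ravel(), np.log(theta.sigma)]
    if spec.family == "EXP-LN":
        parts.append(np.log(theta.rate))
    return np.concatenate(parts)


def backtransform_params(
    z: np.ndarray, spec: ModelSpec, sort: bool = True
) -> ParameterSet:
    """Map an unconstrained vector back to a valid ParameterSet.

    With ``sort=True`` the lognormal populations are relabelled so that the
    first gene's log-means are in decreasing order (ties broken by the
    subsequent genes); probabilities and per-population sigmas are permuted
    along.  The exponential population of EXP-LN always stays last.
    """
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite transformed parameter vector")
    T, m, L = spec.T, spec.m, spec.n_lognormal_pops
    i = 0
    q = z[i : i + T - 1]
    i += T - 1
    p = _softmax_probs(q, T) if T > 1 else np.ones(1)
    mu = z[i : i + L * m].reshape(L, m)
    i += L * m
    sigma = np.exp(z[i : i + spec.n_sigma])
    i += spec.n_sigma
    rate = np.exp(z[i : i + m]) if spec.family == "EXP-LN" else None

    if sort and L > 1:
        # lexicographic: primary key mu^(1) descending, then later genes
        order = np.lexsort(tuple(-mu[:, g] for g in range(m - 1, -1, -1)))
        mu = mu[order]
        p_ln = p[:L][order]
        p = np.concatenate([p_ln, p[L:]])
        if spec.family == "rLN-LN":
            sigma = sigma[order]
    return ParameterSet(p=p, mu=mu, sigma=sigma, rate=rate)


# ---------------------------------------------------------------------------
# search components


def random_search(objective, n_points: int, ranges: np.ndarray, rng) -> list:
    """Evaluate ``objective`` at points drawn uniformly within ``ranges``.

    ``ranges`` is a (d, 2) array of per-coordinate intervals.  Returns the
    list of (point, value) pairs sorted by value descending.
    """
    ranges = np.asarray(ranges, dtype=float)
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    if np.any(ranges[:, 0] > ranges[:, 1]):
        raise ValueError("degenerate search range (lower > upper)")
    pts = rng.uniform(ranges[:, 0], ranges[:, 1], size=(n_points, ranges.shape[0]))
    results = [(pts[j], objective(pts[j])) for j in range(n_points)]
    results.sort(key=lambda t: t[1], reverse=True)
    return results


def _initial_ranges(data: PooledDataset, spec: ModelSpec) -> np.ndarray:
    """Data-adaptive search ranges in the transformed space.

    mu coordinates cover [min, max] of log(y_i / n_i) expanded by +/-2 (the
    log of the per-cell average expression sets the scale); log sigma spans
    [log 0.01, log 2]; simplex coordinates span [-3, 3]; log lambda is
    centred on the reciprocal per-cell mean.
    """
    percell = data.y / data.n[:, None]
    positive = percell[percell > 0]
    if positive.size == 0:
        lo, hi = -1.0, 1.0
    else:
        lo, hi = np.log(positive.min()), np.log(positive.max())
    ranges = [[-3.0, 3.0]] * (spec.T - 1)
    ranges += [[lo - 2.0, hi + 2.0]] * (spec.n_lognormal_pops * spec.m)
    ranges += [[np.log(0.01), np.log(2.0)]] * spec.n_sigma
    if spec.family == "EXP-LN":
        centre = -np.log(max(positive.mean(), 1e-12)) if positive.size else 0.0
        ranges += [[centre - 2.0, centre + 2.0]] * spec.m
    return np.array(ranges, dtype=float)


def _contract_ranges(points: list[np.ndarray], pad: float = 0.2) -> np.ndarray:
    """Bounding box of the given points, padded by ``pad`` of its width."""
    arr = np.asarray(points, dtype=float)
    lo, hi = arr.min(axis=0), arr.max(axis=0)
    width = np.maximum(hi - lo, 1e-3)
    return np.column_stack([lo - pad * width, hi + pad * width])


# ---------------------------------------------------------------------------
# fit result container


@dataclass
class FitResult:
    """Outcome of a maximum-likelihood fit."""

    spec: ModelSpec
    theta_hat: ParameterSet
    z_hat: np.ndarray
    loglik: float
    bic: float
    ci: dict[str, tuple[float | None, float | None]] = field(default_factory=dict)
    trace: list[tuple[int, float]] = field(default_factory=list)
    n_evaluations: int = 0
    converged: bool = False
    seed: int | None = None


def count_parameters(spec: ModelSpec) -> int:
    """Number of free parameters of the model.

    LN-LN: (T-1) + T*m + 1 = T(m+1); rLN-LN: (T-1) + T*m + T;
    EXP-LN: (T-1) + (T-1)*m + 1 + m.
    """
    extra = spec.m if spec.family == "EXP-LN" else 0
    return (spec.T - 1) + spec.n_lognormal_pops * spec.m + spec.n_sigma + extra


def bic(loglik: float, n_params: int, k: int) -> float:
    """Bayesian information criterion, -2*loglik + log(k)*n_params."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return -2.0 * loglik + np.log(k) * n_params


# ---------------------------------------------------------------------------
# the fit itself


def fit_maximum_likelihood(
    data: PooledDataset,
    spec: ModelSpec,
    loops: int = 5,
    until_convergence: bool = False,
    rng_seed: int | None = None,
    n_grid: int = 500,
    n_top: int = 5,
    nm_maxiter: int | None = None,
    extra_starts: list[ParameterSet] | None = None,
    compute_ci: bool = True,
) -> FitResult:
    """Fit a pooled mixture model by maximum likelihood.

    Each outer loop runs three rounds of randomized grid search followed by
    Nelder--Mead restarts from the best points, contracting the search
    ranges around the local maxima.  The best point across all loops is
    returned.  With ``until_convergence`` the loops stop once the
    improvement falls below 5e-5.

    ``extra_starts`` seeds additional Nelder--Mead runs (used by
    :func:`staged_fit` to pass estimates from smaller gene subsets).
    """
    data.check_support(spec)
    if data.k < 10:
        warnings.warn(
            f"only {data.k} samples; estimates will be unstable", UserWarning
        )
    rng = np.random.default_rng(rng_seed)
    n_eval = 0

    def objective(z: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        try:
            with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
                theta = backtransform_params(z, spec)
                val = log_likelihood(theta, data, spec)
        except (ValueError, FloatingPointError):
            return -np.inf
        return val if np.isfinite(val) else -np.inf

    def neg(z: np.ndarray) -> float:
        v = objective(z)
        return -v if np.isfinite(v) else 1e12

    init_ranges = _initial_ranges(data, spec)
    d = init_ranges.shape[0]
    maxiter = nm_maxiter if nm_maxiter is not None else 200 * d

    best_z, best_val = None, -np.inf
    trace: list[tuple[int, float]] = []
    converged = False

    seeds = [transform_params(t, spec) for t in (extra_starts or [])]

    for loop in range(loops):
        ranges = init_ranges
        prev_best = best_val
        for _round in range(3):
            results = random_search(objective, n_grid, ranges, rng)
            starts = [pt for pt, val in results[:n_top] if np.isfinite(val)]
            if loop == 0 and _round == 0:
                starts += seeds
            if not starts:
                continue
            local_optima = []
            for x0 in starts:
                res = minimize(
                    neg,
                    x0,
                    method="Nelder-Mead",
                    options={"maxiter": maxiter, "xatol": 1e-4, "fatol": 1e-6},
                )
                local_optima.append((res.x, -res.fun))
                if -res.fun > best_val:
                    best_val, best_z = -res.fun, res.x.copy()
            ranges = _contract_ranges([x for x, _ in local_optima])
        trace.append((loop, best_val))
        if not np.isfinite(best_val):
            continue
        if until_convergence and loop > 0 and best_val - prev_best < CONVERGENCE_TOL:
            converged = True
            break

    if best_z is None or not np.isfinite(best_val):
        raise RuntimeError(
            "maximum-likelihood fit failed: every likelihood evaluation was "
            "-inf (zeros in the data under a lognormal-only family are the "
            "most common cause)"
        )

    theta_hat = backtransform_params(best_z, spec)
    # re-express the optimum in sorted labelling so CIs refer to it
    z_sorted = transform_params(theta_hat, spec)
    fit = FitResult(
        spec=spec,
        theta_hat=theta_hat,
        z_hat=z_sorted,
        loglik=float(best_val),
        bic=bic(best_val, count_parameters(spec), data.k),
        trace=trace,
        n_evaluations=n_eval,
        converged=converged or not until_convergence,
        seed=rng_seed,
    )
    if compute_ci:
        fit.ci = confidence_intervals(fit, data, spec)
    return fit


def staged_fit(
    data: PooledDataset,
    spec: ModelSpec,
    rng_seed: int | None = None,
    subset_size: int = 1,
    **fit_kwargs,
) -> FitResult:
    """Fit many genes by first fitting small gene subsets, then seeding the
    joint fit with the per-subset estimates (helps the multimodal search in
    high dimension)."""
    if spec.m == 1:
        return fit_maximum_likelihood(data, spec, rng_seed=rng_seed, **fit_kwargs)
    ss = np.random.SeedSequence(rng_seed).spawn(spec.m + 1)
    sub_kwargs = {k: v for k, v in fit_kwargs.items() if k != "compute_ci"}
    mus, sigmas, ps, rates = [], [], [], []
    for g0 in range(0, spec.m, subset_size):
        genes = list(range(g0, min(g0 + subset_size, spec.m)))
        sub_spec = ModelSpec(spec.family, spec.T, len(genes))
        sub_data = PooledDataset(data.y[:, genes], data.n)
        sub = fit_maximum_likelihood(
            sub_data,
            sub_spec,
            rng_seed=int(ss[g0].generate_state(1)[0] % 2**31),
            compute_ci=False,
            **sub_kwargs,
        )
        mus.append(sub.theta_hat.mu)
        sigmas.append(sub.theta_hat.sigma)
        ps.append(sub.theta_hat.p)
        if sub.theta_hat.rate is not None:
            rates.append(sub.theta_hat.rate)
    start = ParameterSet(
        p=np.mean(ps, axis=0) / np.sum(np.mean(ps, axis=0)),
        mu=np.hstack(mus),
        sigma=np.mean(sigmas, axis=0),
        rate=np.concatenate(rates) if rates else None,
    )
    return fit_maximum_likelihood(
        data,
        spec,
        rng_seed=int(ss[-1].generate_state(1)[0] % 2**31),
        extra_starts=[start],
        **fit_kwargs,
    )


# ---------------------------------------------------------------------------
# confidence intervals


def _hessian_central(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central finite-difference Hessian with a relative step."""
    x = np.asarray(x, dtype=float)
    d = x.size
    h = rel_step * np.maximum(np.abs(x), 1.0)
    H = np.empty((d, d))
    f0 = f(x)
    for i in range(d):
        ei = np.zeros(d)
        ei[i] = h[i]
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / h[i] ** 2
        for j in range(i + 1, d):
            ej = np.zeros(d)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def _component_backtransform(
    z_hat: np.ndarray, i: int, value: float, spec: ModelSpec
) -> float:
    """Back-transform a bound on the i-th transformed coordinate, holding the
    other coordinates at the optimum, and read off the natural parameter the
    coordinate governs."""
    z = z_hat.copy()
    z[i] = value
    theta = backtransform_params(z, spec, sort=False)
    T, m, L = spec.T, spec.m, spec.n_lognormal_pops
    if i < T - 1:
        return float(theta.p[i])
    i2 = i - (T - 1)
    if i2 < L * m:
        return float(theta.mu.ravel()[i2])
    i3 = i2 - L * m
    if i3 < spec.n_sigma:
        return float(theta.sigma[i3])
    return float(theta.rate[i3 - spec.n_sigma])


def confidence_intervals(
    fit: FitResult, data: PooledDataset, spec: ModelSpec
) -> dict[str, tuple[float | None, float | None]]:
    """Approximate marginal 95% confidence intervals on the original scale.

    Computes the Hessian of the negative log-likelihood at the transformed
    optimum by central finite differences; d_i is the i-th diagonal element
    of its inverse.  Bounds z_i +/- 1.96 sqrt(d_i) are back-transformed
    componentwise.  Components with a non-positive-definite curvature get
    (None, None) bounds with a warning.
    """

    def negll(z):
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            try:
                return -log_likelihood(backtransform_params(z, spec, sort=False), data, spec)
            except (ValueError, FloatingPointError):
                return np.inf

    z_hat = fit.z_hat
    H = _hessian_central(negll, z_hat)
    names = param_names(spec)
    ci: dict[str, tuple[float | None, float | None]] = {}
    try:
        Hinv = np.linalg.inv(H)
        diag = np.diag(Hinv)
    except np.linalg.LinAlgError:
        diag = np.full(z_hat.size, -1.0)
    bad = ~(np.isfinite(diag) & (diag >= 0))
    if np.any(bad):
        warnings.warn(
            "Hessian is not positive definite; confidence bounds unavailable "
            f"for {[names[i] for i in np.where(bad)[0]]}",
            UserWarning,
        )
    for i, name in enumerate(names):
        if bad[i]:
            ci[name] = (None, None)
            continue
        half = 1.96 * np.sqrt(diag[i])
        lo = _component_backtransform(z_hat, i, z_hat[i] - half, spec)
        hi = _component_backtransform(z_hat, i, z_hat[i] + half, spec)
        ci[name] = (min(lo, hi), max(lo, hi))
    return ci


# ---------------------------------------------------------------------------
# model selection


def select_model(
    data: PooledDataset,
    candidates: list[ModelSpec],
    rng_seed: int | None = None,
    **fit_kwargs,
) -> list[FitResult]:
    """Fit every candidate model and rank the results by BIC (ascending).

    Candidates whose fit fails are excluded with a warning.  Each candidate
    gets its own deterministic sub-seed so rankings are reproducible.
    """
    if len(candidates) < 2:
        raise ValueError("model selection needs at least two candidates")
    ss = np.random.SeedSequence(rng_seed).spawn(len(candidates))
    fits = []
    for cand, child in zip(candidates, ss):
        try:
            fits.append(
                fit_maximum_likelihood(
                    data,
                    cand,
                    rng_seed=int(child.generate_state(1)[0] % 2**31),
                    **fit_kwargs,
                )
            )
        except (RuntimeError, ValueError) as err:
            warnings.warn(
                f"candidate {cand.family} T={cand.T} failed to fit: {err}",
                UserWarning,
            )
    fits.sort(key=lambda f: f.bic)
    return fits
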