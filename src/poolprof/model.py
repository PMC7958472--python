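"""Mixture-convolution density of pooled observations and the log-likelihood.

Observed pooled expression ``y_i = sum of n_i single-cell values``.  Each
cell belongs to one of ``T`` latent populations with probabilities ``p``;
conditionally on a pool *composition* (how many cells of each population the
pool contains) the pooled density is a convolution of the per-population
densities.  Marginally,

    f_n(y | theta, p) = sum over compositions l of
        multinomial(l; n, p) * f_l(y | theta),

where the sum runs over all C(n+T-1, T-1) compositions of n cells into T
populations.  Three families are supported:

* ``LN-LN``   -- every population lognormal, shared log-sd sigma;
* ``rLN-LN``  -- every population lognormal, population-specific sigma_h;
* ``EXP-LN``  -- the last population exponential (rate per gene), the other
  T-1 populations lognormal with shared sigma.

Log-sd values are shared across genes in all families; log-means (and
exponential rates) are gene-specific.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.special import gammaln, logsumexp, xlogy

from .distributions import (
    erlang_logpdf,
    fw_combine_counts,
    lognormal_logpdf,
)

# Gauss-Legendre rule for the Erlang (x) lognormal convolution integral on
# [0, y]; 96 nodes resolve the single interior peak to ~1e-10 for the
# log-sd range the models use
_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(96)

FAMILIES = ("LN-LN", "rLN-LN", "EXP-LN")

#: floor for a single log-density term; keeps the objective finite where the
#: density underflows to zero (exp(-745) is the smallest normal double)
LOG_FLOOR = -745.0


@dataclass(frozen=True)
class ModelSpec:
    """Model family, number of populations T and number of genes m."""

    family: str
    T: int
    m: int = 1

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if self.m < 1:
            raise ValueError("m must be >= 1")

    @property
    def n_lognormal_pops(self) -> int:
        """Number of lognormal populations (the EXP-LN family reserves the last
        population for the exponential component)."""
        return self.T - 1 if self.family == "EXP-LN" else self.T

    @property
    def n_sigma(self) -> int:
        if self.family == "rLN-LN":
            return self.T
        return 1 if self.n_lognormal_pops > 0 else 0


@dataclass
class ParameterSet:
    """All model parameters for one :class:`ModelSpec`.

    p      : (T,) population probabilities, summing to one.
    mu     : (n_lognormal_pops, m) log-means mu_h^{(g)}.
    sigma  : (1,) shared log-sd, or (T,) per-population log-sds (rLN-LN).
    rate   : (m,) exponential rates lambda^{(g)} (EXP-LN only), else None.
    """

    p: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    rate: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.p = np.atleast_1d(np.asarray(self.p, dtype=float))
        self.mu = np.atleast_2d(np.asarray(self.mu, dtype=float))
        self.sigma = np.atleast_1d(np.asarray(self.sigma, dtype=float))
        if self.rate is not None:
            self.rate = np.atleast_1d(np.asarray(self.rate, dtype=float))

    def validate(self, spec: ModelSpec) -> None:
        if self.p.shape != (spec.T,):
            raise ValueError(f"p must have shape ({spec.T},), got {self.p.shape}")
        if np.any(self.p < 0) or np.any(self.p > 1) or abs(self.p.sum() - 1.0) > 1e-8:
            raise ValueError("p must lie in [0,1] and sum to 1")
        expect_mu = (spec.n_lognormal_pops, spec.m)
        if self.mu.shape != expect_mu:
            raise ValueError(f"mu must have shape {expect_mu}, got {self.mu.shape}")
        if self.sigma.shape != (spec.n_sigma,):
            raise ValueError(
                f"sigma must have shape ({spec.n_sigma},), got {self.sigma.shape}"
            )
        if np.any(self.sigma <= 0):
            raise ValueError("all sigma must be > 0")
        if spec.family == "EXP-LN":
            if self.rate is None or self.rate.shape != (spec.m,):
                raise ValueError(f"rate must have shape ({spec.m},) for EXP-LN")
            if np.any(self.rate <= 0):
                raise ValueError("all rates must be > 0")
        elif self.rate is not None:
            raise ValueError(f"rate is only meaningful for EXP-LN, not {spec.family}")

    def sigma_per_lognormal_pop(self, spec: ModelSpec) -> np.ndarray:
        """Log-sd of each lognormal population, broadcast from the shared value
        where the family uses one."""
        L = spec.n_lognormal_pops
        if spec.family == "rLN-LN":
            return self.sigma
        return np.full(L, self.sigma[0]) if L else np.empty(0)


@dataclass
class PooledDataset:
    """Pooled expression matrix (k samples x m genes) with pool sizes.

    ``latent_compositions`` (k x T) records the true per-pool population
    counts when the dataset was simulated; it is None for real data.
    """

    y: np.ndarray
    n: np.ndarray
    gene_names: list[str] | None = None
    latent_compositions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.y = np.atleast_2d(np.asarray(self.y, dtype=float))
        self.n = np.atleast_1d(np.asarray(self.n, dtype=int))
        if self.y.shape[0] != self.n.shape[0]:
            raise ValueError(
                f"pool-size vector length {self.n.shape[0]} does not match "
                f"number of samples {self.y.shape[0]}"
            )
        if np.any(self.n < 1):
            raise ValueError("all pool sizes must be >= 1")
        if np.any(np.isnan(self.y)):
            raise ValueError("NaN values in expression matrix")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("non-finite values in expression matrix")
        if np.any(self.y < 0):
            raise ValueError("negative expression values are not allowed")
        if self.gene_names is None:
            self.gene_names = [f"gene{g + 1}" for g in range(self.y.shape[1])]

    @property
    def k(self) -> int:
        return self.y.shape[0]

    @property
    def m(self) -> int:
        return self.y.shape[1]

    def check_support(self, spec: ModelSpec) -> None:
        """Zeros are outside the lognormal support; reject them early for the
        LN-only families instead of silently offsetting the data."""
        if spec.family in ("LN-LN", "rLN-LN") and np.any(self.y <= 0):
            raise ValueError(
                "zero (or negative) pooled values cannot be modelled by the "
                f"{spec.family} family: add a small offset to the data "
                "(e.g. 0.0001) or use the EXP-LN family"
            )


@lru_cache(maxsize=256)
def _compositions_cached(n: int, T: int) -> np.ndarray:
    if T == 1:
        return np.array([[n]], dtype=np.int64)
    rows = []
    for l1 in range(n + 1):
        tail = _compositions_cached(n - l1, T - 1)
        block = np.empty((tail.shape[0], T), dtype=np.int64)
        block[:, 0] = l1
        block[:, 1:] = tail
        rows.append(block)
    return np.vstack(rows)


def enumerate_compositions(n: int, T: int) -> np.ndarray:
    """All compositions of ``n`` cells into ``T`` populations.

    Returns an integer array of shape (C(n+T-1, T-1), T), lexicographically
    ordered, each row summing to ``n``.  Memoized per (n, T).
    """
    if n < 1 or T < 1:
        raise ValueError("n and T must be >= 1")
    return _compositions_cached(int(n), int(T))


def multinomial_log_weights(comps: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Log multinomial probabilities of the rows of ``comps`` under ``p``.

    Computed via log-gamma so that n = 50 does not overflow; xlogy handles
    boundary probabilities (p_h = 0 with l_h = 0 contributes nothing).
    """
    comps = np.asarray(comps)
    n = comps[0].sum()
    return (
        gammaln(n + 1)
        - gammaln(comps + 1).sum(axis=1)
        + xlogy(comps, np.asarray(p, dtype=float)).sum(axis=1)
    )


def multinomial_weight(comp, p) -> float:
    """Multinomial probability of one composition under population probabilities p."""
    comp = np.atleast_2d(np.asarray(comp, dtype=np.int64))
    p = np.asarray(p, dtype=float)
    if comp.shape[1] != p.shape[0]:
        raise ValueError("composition and probability vector lengths differ")
    return float(np.exp(multinomial_log_weights(comp, p)[0]))


def composition_logpdf_matrix(
    y: np.ndarray,
    comps: np.ndarray,
    theta: ParameterSet,
    gene: int,
    spec: ModelSpec,
) -> np.ndarray:
    """Log-density of each observation under each fixed pool composition.

    Returns an array of shape (C, k) with entry (c, i) = log f_{l_c}(y_i).
    The lognormal cells of a composition are first collapsed into a single
    moment-matched lognormal; for EXP-LN the result is then convolved once
    with the Erlang part of the exponential cells.
    """
    y = np.atleast_1d(np.asarray(y, dtype=float))
    comps = np.atleast_2d(comps)
    L = spec.n_lognormal_pops
    sig = theta.sigma_per_lognormal_pop(spec)
    mu_g = theta.mu[:, gene] if L else np.empty(0)

    if spec.family != "EXP-LN":
        mb, sb = fw_combine_counts(comps, mu_g, sig)
        return lognormal_logpdf(y[None, :], mb[:, None], sb[:, None])

    rate = float(theta.rate[gene])
    ln_counts = comps[:, :L]
    n_exp = comps[:, L]
    out = np.empty((comps.shape[0], y.shape[0]))
    has_ln = ln_counts.sum(axis=1) > 0
    mb, sb = fw_combine_counts(ln_counts, mu_g, sig) if L else (None, None)
    for c in range(comps.shape[0]):
        if n_exp[c] == 0:
            out[c] = lognormal_logpdf(y, mb[c], sb[c])
        elif not has_ln[c]:
            out[c] = erlang_logpdf(y, int(n_exp[c]), rate)
        else:
            # convolution of Erlang(n_exp, rate) with the collapsed lognormal,
            # integrated on [0, y] by fixed Gauss-Legendre quadrature
            pos = y > 0
            yp = y[pos]
            t = 0.5 * yp[None, :] * (_GL_NODES[:, None] + 1.0)
            integrand = np.exp(
                erlang_logpdf(t, int(n_exp[c]), rate)
                + lognormal_logpdf(yp[None, :] - t, mb[c], sb[c])
            )
            pdf = 0.5 * yp * (_GL_WEIGHTS[:, None] * integrand).sum(axis=0)
            row = np.full(y.shape[0], -np.inf)
            with np.errstate(divide="ignore"):
                row[pos] = np.log(np.maximum(pdf, 0.0))
            out[c] = row
    return out


def composition_pdf(y, comp, theta: ParameterSet, gene: int, spec: ModelSpec):
    """Density of a pooled value given a known composition of the pool."""
    comp = np.atleast_1d(np.asarray(comp, dtype=np.int64))
    if comp.sum() == 0:
        raise ValueError("composition must contain at least one cell")
    scalar = np.ndim(y) == 0
    res = np.exp(
        composition_logpdf_matrix(np.atleast_1d(y), comp[None, :], theta, gene, spec)
    )[0]
    return float(res[0]) if scalar else res


def pooled_logpdf(
    y: np.ndarray, n: int, theta: ParameterSet, gene: int, spec: ModelSpec
) -> np.ndarray:
    """Vectorized log of the pooled density f_n(y | theta, p) for one gene."""
    comps = enumerate_compositions(n, spec.T)
    log_w = multinomial_log_weights(comps, theta.p)
    keep = log_w > -np.inf
    log_f = composition_logpdf_matrix(
        np.atleast_1d(y), comps[keep], theta, gene, spec
    )
    return logsumexp(log_w[keep][:, None] + log_f, axis=0)


def pooled_pdf(y, n: int, theta: ParameterSet, gene: int, spec: ModelSpec):
    """Marginal density of a pooled observation (sum over all compositions).

    For n = 1 this reduces to the single-cell mixture density; for T = 1 it
    is the density of the single population's n-fold convolution.
    """
    scalar = np.ndim(y) == 0
    res = np.exp(pooled_logpdf(np.atleast_1d(y), n, theta, gene, spec))
    return float(res[0]) if scalar else res


def log_likelihood(theta: ParameterSet, data: PooledDataset, spec: ModelSpec) -> float:
    """Joint log-likelihood: sum over genes and samples of log f_{n_i}(y_i^{(g)}).

    Genes are assumed independent.  Each term is floored at ``LOG_FLOOR`` so
    the objective stays finite for the optimizer even where the density
    underflows.
    """
    theta.validate(spec)
    if data.m != spec.m:
        raise ValueError(f"dataset has {data.m} genes but spec.m = {spec.m}")
    total = 0.0
    for n in np.unique(data.n):
        idx = data.n == n
        for g in range(spec.m):
            lp = pooled_logpdf(data.y[idx, g], int(n), theta, g, spec)
            total += float(np.maximum(lp, LOG_FLOOR).sum())
    return total
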