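"""Elementary densities and the two convolution building blocks.

Pools of cells are sums of independent single-cell expression values.  Two
primitives make the pooled densities tractable:

* a sum of independent lognormals has no closed-form density; it is
  approximated by a single lognormal whose mean and variance equal those of
  the sum exactly (Fenton--Wilkinson moment matching);
* a sum of i.i.d. exponentials is Erlang (gamma with integer shape), and its
  convolution with a lognormal is computed by adaptive quadrature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import integrate
from scipy.special import gammaln

_LOG_2PI = float(np.log(2.0 * np.pi))


class InvalidParameterError(ValueError):
    """A distribution parameter violates its constraint (e.g. sigma <= 0)."""


@dataclass(frozen=True)
class LognormalParams:
    """Log-mean and log-standard-deviation of a lognormal distribution.

    ``mu`` and ``sigma`` are the mean and standard deviation of the natural
    logarithm of the variable; ``sigma`` must be strictly positive.
    """

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.mu):
            raise InvalidParameterError(f"mu must be finite, got {self.mu}")
        if not (self.sigma > 0) or not np.isfinite(self.sigma):
            raise InvalidParameterError(f"sigma must be > 0, got {self.sigma}")


@dataclass(frozen=True)
class ExponentialParams:
    """Rate parameter of an exponential distribution (1/expression units)."""

    rate: float

    def __post_init__(self) -> None:
        if not (self.rate > 0) or not np.isfinite(self.rate):
            raise InvalidParameterError(f"rate must be > 0, got {self.rate}")


def lognormal_logpdf(x, mu, sigma):
    """Vectorized log-density of LN(mu, sigma^2); -inf for x <= 0."""
    x = np.asarray(x, dtype=float)
    out = np.full(np.broadcast_shapes(x.shape, np.shape(mu), np.shape(sigma)),
                  -np.inf, dtype=float)
    pos = np.broadcast_to(x > 0, out.shape)
    lx = np.log(np.where(x > 0, x, 1.0))
    z = (lx - mu) / sigma
    val = -0.5 * z * z - np.log(sigma) - 0.5 * _LOG_2PI - lx
    out[pos] = np.broadcast_to(val, out.shape)[pos]
    return out


def lognormal_pdf(x, params: LognormalParams):
    """Density of LN(mu, sigma^2) at ``x``; zero on the non-positive axis."""
    res = np.exp(lognormal_logpdf(x, params.mu, params.sigma))
    if np.ndim(x) == 0:
        return float(res)
    return res


def lognormal_moments(params: LognormalParams) -> tuple[float, float, float]:
    """Mean, variance and coefficient of variation of LN(mu, sigma^2).

    mean = exp(mu + sigma^2/2); var = exp(2 mu + sigma^2)(exp(sigma^2) - 1);
    cv = sqrt(exp(sigma^2) - 1), which does not depend on mu.
    """
    mu, s2 = params.mu, params.sigma**2
    mean = np.exp(mu + s2 / 2.0)
    var = np.exp(2.0 * mu + s2) * (np.exp(s2) - 1.0)
    cv = np.sqrt(np.exp(s2) - 1.0)
    return float(mean), float(var), float(cv)


def exponential_pdf(x, params: ExponentialParams):
    """Density lambda * exp(-lambda x) for x >= 0, zero for x < 0."""
    x = np.asarray(x, dtype=float)
    out = np.where(x >= 0, params.rate * np.exp(-params.rate * x), 0.0)
    if np.ndim(x) == 0 and out.ndim == 0:
        return float(out)
    return out


def fenton_wilkinson_combine(summands: list[LognormalParams]) -> LognormalParams:
    """Moment-matched lognormal approximation to a sum of lognormals.

    The returned LN(mu_B, sigma_B^2) has mean Gamma = sum of summand means and
    variance Delta = sum of summand variances, exactly:
    sigma_B^2 = log(Delta / Gamma^2 + 1), mu_B = log(Gamma) - sigma_B^2 / 2.
    """
    if not summands:
        raise ValueError("fenton_wilkinson_combine requires at least one summand")
    mus = np.array([s.mu for s in summands])
    s2 = np.array([s.sigma for s in summands]) ** 2
    gamma = np.sum(np.exp(mus + s2 / 2.0))
    delta = np.sum(np.exp(2.0 * mus + s2) * (np.exp(s2) - 1.0))
    sb2 = np.log(delta / gamma**2 + 1.0)
    mb = np.log(gamma) - sb2 / 2.0
    return LognormalParams(float(mb), float(np.sqrt(sb2)))


def fw_combine_counts(counts, mu, sigma):
    """Fenton--Wilkinson combination of ``counts[h]`` copies of LN(mu[h], sigma[h]^2).

    Vectorized over leading axes of ``counts`` (shape (..., H)).  Returns
    ``(mu_B, sigma_B)`` arrays of shape ``counts.shape[:-1]``.  Rows whose
    counts are all zero yield NaN and must be handled by the caller.
    """
    counts = np.asarray(counts, dtype=float)
    mu = np.asarray(mu, dtype=float)
    s2 = np.asarray(sigma, dtype=float) ** 2
    means = np.exp(mu + s2 / 2.0)
    varis = np.exp(2.0 * mu + s2) * (np.exp(s2) - 1.0)
    gamma = counts @ means
    delta = counts @ varis
    with np.errstate(divide="ignore", invalid="ignore"):
        sb2 = np.log(delta / gamma**2 + 1.0)
        mb = np.log(gamma) - sb2 / 2.0
    return mb, np.sqrt(sb2)


def erlang_logpdf(x, shape, rate):
    """Vectorized log-density of the Erlang(shape, rate) distribution."""
    x = np.asarray(x, dtype=float)
    out = np.full(x.shape if x.ndim else (), -np.inf, dtype=float)
    ok = x > 0
    lx = np.log(np.where(ok, x, 1.0))
    val = shape * np.log(rate) + (shape - 1) * lx - rate * x - gammaln(shape)
    if x.ndim == 0:
        if shape == 1 and x >= 0:
            return float(np.log(rate) - rate * x)
        return float(val) if ok else -np.inf
    out = np.where(ok, val, -np.inf)
    if shape == 1:
        out = np.where(x == 0, np.log(rate), out)
    return out


def erlang_pdf(x, shape: int, rate: float):
    """Gamma density with integer shape; shape 1 reduces to the exponential."""
    if shape != int(shape) or shape < 1:
        raise InvalidParameterError(f"shape must be a positive integer, got {shape}")
    if not (rate > 0):
        raise InvalidParameterError(f"rate must be > 0, got {rate}")
    res = np.exp(erlang_logpdf(x, int(shape), rate))
    if np.ndim(x) == 0:
        return float(res)
    return res


def exp_lognormal_convolution_pdf(
    y,
    n_exp: int,
    rate: float,
    ln_part: LognormalParams | None = None,
) -> float:
    """Density of (sum of ``n_exp`` i.i.d. exponentials) + one lognormal.

    The exponential part is Erlang(n_exp, rate); the lognormal part is the
    moment-matched summary of all lognormal cells in the pool (or ``None``
    for a pool without lognormal cells, in which case the density is pure
    Erlang).  The convolution integral over [0, y] has no closed form and is
    evaluated by adaptive Gauss--Kronrod quadrature (abs. tol 1e-10, rel.
    1e-8); the integrand is smooth with a single interior peak.
    """
    if n_exp != int(n_exp) or n_exp < 1:
        raise InvalidParameterError(f"n_exp must be a positive integer, got {n_exp}")
    if not (rate > 0):
        raise InvalidParameterError(f"rate must be > 0, got {rate}")
    y = float(y)
    if y < 0:
        return 0.0
    if ln_part is None:
        return erlang_pdf(y, int(n_exp), rate)
    if y == 0.0:
        return 0.0
    mu, sigma = ln_part.mu, ln_part.sigma

    def integrand(t):
        return np.exp(
            erlang_logpdf(t, int(n_exp), rate)
            + lognormal_logpdf(y - t, mu, sigma)
        )

    with warnings.catch_warnings():
        warnings.simplefilter("error", integrate.IntegrationWarning)
        try:
            val, _ = integrate.quad(
                integrand, 0.0, y, epsabs=1e-10, epsrel=1e-8, limit=200
            )
        except integrate.IntegrationWarning:
            warnings.simplefilter("default", integrate.IntegrationWarning)
            warnings.warn(
                "EXP-LN convolution quadrature did not fully converge; "
                "returning best estimate",
                RuntimeWarning,
                stacklevel=2,
            )
            val, _ = integrate.quad(integrand, 0.0, y, limit=500)
    return max(float(val), 0.0)
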