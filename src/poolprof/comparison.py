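"""Overlap coefficient of inferred populations and a sampling-based equality test.

The overlap coefficient OVL(f, g) = integral of min{f, g} is an
interpretable similarity of two densities (1 for identical, 0 for
disjoint).  For two lognormals it equals the overlap of the corresponding
normals on the log scale (OVL is invariant under strictly monotone axis
transformations), which is available in closed form: 2*Phi(-|dmu|/(2*sigma))
for equal sigma, and via the two crossing points of the quadratic
log-density difference otherwise.

Whether an observed OVL is *small enough* to call two inferred populations
different depends on how much data the estimates relied on.  The test
simulates the null (both populations identical, parameters averaged):
repeatedly draw the two groups' effective cell counts of single-cell values
from the pooled-null lognormal, refit each group, and record the OVL of the
refitted pair.  The original OVL is compared against the empirical 5%
quantile of these null overlaps.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .distributions import LognormalParams


def _normal_ovl_vec(mu1, s1, mu2, s2):
    """Vectorized overlap of N(mu1, s1^2) and N(mu2, s2^2)."""
    mu1, s1, mu2, s2 = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (mu1, s1, mu2, s2))
    )
    out = np.empty(mu1.shape)
    eq = np.abs(s1 - s2) <= 1e-12 * np.maximum(s1, s2)
    # equal spread: single crossing at the midpoint
    if np.any(eq):
        out[eq] = 2.0 * norm.cdf(-np.abs(mu1[eq] - mu2[eq]) / (2.0 * s1[eq]))
    ne = ~eq
    if np.any(ne):
        m1, sd1, m2, sd2 = mu1[ne], s1[ne], mu2[ne], s2[ne]
        a = 1.0 / sd2**2 - 1.0 / sd1**2
        b = -2.0 * (m2 / sd2**2 - m1 / sd1**2)
        c = m2**2 / sd2**2 - m1**2 / sd1**2 + 2.0 * np.log(sd2 / sd1)
        disc = np.sqrt(np.maximum(b**2 - 4.0 * a * c, 0.0))
        r1 = (-b - disc) / (2.0 * a)
        r2 = (-b + disc) / (2.0 * a)
        x1, x2 = np.minimum(r1, r2), np.maximum(r1, r2)

        def min_mass(lo, hi):
            """Probability mass of the pointwise-smaller density on (lo, hi)."""
            mid = np.where(
                np.isneginf(lo),
                hi - 1.0,
                np.where(np.isposinf(hi), lo + 1.0, 0.5 * (lo + hi)),
            )
            f1 = norm.logpdf(mid, m1, sd1)
            f2 = norm.logpdf(mid, m2, sd2)
            use1 = f1 <= f2
            mu = np.where(use1, m1, m2)
            sd = np.where(use1, sd1, sd2)
            lo_z = np.where(np.isneginf(lo), -np.inf, (lo - mu) / sd)
            hi_z = np.where(np.isposinf(hi), np.inf, (hi - mu) / sd)
            return norm.cdf(hi_z) - norm.cdf(lo_z)

        ninf = np.full_like(x1, -np.inf)
        pinf = np.full_like(x1, np.inf)
        out[ne] = min_mass(ninf, x1) + min_mass(x1, x2) + min_mass(x2, pinf)
    return np.clip(out, 0.0, 1.0)


def ovl(f_params: LognormalParams, g_params: LognormalParams) -> float:
    """Overlap coefficient of two lognormal densities, in [0, 1]."""
    return float(
        _normal_ovl_vec(f_params.mu, f_params.sigma, g_params.mu, g_params.sigma)
    )


def effective_cell_count(p_hat: float, k: int, pool_sizes) -> int:
    """Number of single cells an estimate for one population relied on:
    round(p_hat * total cells across all pools)."""
    pool_sizes = np.atleast_1d(np.asarray(pool_sizes, dtype=float))
    total = float(pool_sizes.sum()) if pool_sizes.size > 1 else float(
        pool_sizes[0] * k
    )
    return int(np.rint(p_hat * total))


@dataclass
class OverlapTestResult:
    """Result of the sampling-based population-equality test."""

    ovl_original: float
    null_ovls: np.ndarray
    q05: float
    reject: bool
    cells_a: int
    cells_b: int


def overlap_null_test(
    est_a: tuple[LognormalParams, int],
    est_b: tuple[LognormalParams, int],
    N: int = 1000,
    rng_seed: int | None = None,
) -> OverlapTestResult:
    """Test whether two inferred lognormal populations are the same.

    ``est_a`` and ``est_b`` are (fitted lognormal parameters, effective cell
    count) per group.  Under the null the groups share one distribution,
    approximated by averaging log-means and log-sds.  N replicates draw
    cells_a and cells_b single-cell values from that null lognormal, refit
    each set by maximum likelihood (sample mean and sd of the logs), and
    record the OVL of the refitted pair.  The null is rejected when the
    original OVL falls at or below the empirical 5% quantile (lower order
    statistic, index ceil(0.05 N)).
    """
    (pa, cells_a), (pb, cells_b) = est_a, est_b
    if cells_a < 2 or cells_b < 2:
        raise ValueError("need at least 2 cells per group to refit a lognormal")
    if N < 100:
        warnings.warn(
            f"N={N} null replicates make the 5% quantile unstable", UserWarning
        )
    rng = np.random.default_rng(rng_seed)
    ovl_original = ovl(pa, pb)
    mu0 = 0.5 * (pa.mu + pb.mu)
    sd0 = 0.5 * (pa.sigma + pb.sigma)

    logs_a = rng.normal(mu0, sd0, size=(N, cells_a))
    logs_b = rng.normal(mu0, sd0, size=(N, cells_b))
    mu_a, sd_a = logs_a.mean(axis=1), logs_a.std(axis=1)
    mu_b, sd_b = logs_b.mean(axis=1), logs_b.std(axis=1)
    null_ovls = _normal_ovl_vec(mu_a, sd_a, mu_b, sd_b)

    order = np.sort(null_ovls)
    q05 = float(order[math.ceil(0.05 * N) - 1])
    return OverlapTestResult(
        ovl_original=ovl_original,
        null_ovls=null_ovls,
        q05=q05,
        reject=bool(ovl_original <= q05),
        cells_a=int(cells_a),
        cells_b=int(cells_b),
    )
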