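"""Conditional prediction of per-pool population compositions.

Given fitted (or true) model parameters, the posterior probability of a
pool's composition l given its pooled measurements y is

    P(l | y) proportional to  multinomial(l; n, p) * prod_g f_l(y^(g) | theta),

normalized over all compositions of the pool size.  The per-gene densities
multiply because genes are conditionally independent given the (shared)
composition.  All products are accumulated as sums of logs with a single
max-shift normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .model import (
    ModelSpec,
    ParameterSet,
    PooledDataset,
    composition_logpdf_matrix,
    enumerate_compositions,
    multinomial_log_weights,
)


@dataclass
class CompositionPosterior:
    """Posterior over the compositions of one pool."""

    pool_index: int
    support: np.ndarray          # (C, T) integer compositions
    probs: np.ndarray            # (C,) posterior probabilities, sum to 1
    mle: np.ndarray              # argmax composition
    mean_counts: np.ndarray      # posterior mean count per population
    credible_set: np.ndarray     # smallest set with total probability >= 0.95

    @property
    def entropy(self) -> float:
        p = self.probs[self.probs > 0]
        return float(-(p * np.log(p)).sum())


def _credible_set(support: np.ndarray, probs: np.ndarray, level: float = 0.95):
    # descending probability, ties broken by smaller count in population 1
    order = np.lexsort((support[:, 0], -probs))
    cum = np.cumsum(probs[order])
    stop = int(np.searchsorted(cum, level) + 1)
    return support[order[:stop]]


def composition_posterior(
    y_row,
    n: int,
    theta: ParameterSet,
    spec: ModelSpec,
    pool_index: int = 0,
) -> CompositionPosterior:
    """Posterior over compositions of one pool given its m pooled values."""
    y_row = np.atleast_1d(np.asarray(y_row, dtype=float))
    if y_row.shape[0] != spec.m:
        raise ValueError(f"expected {spec.m} pooled values, got {y_row.shape[0]}")
    theta.validate(spec)
    support = enumerate_compositions(n, spec.T)
    logpost = multinomial_log_weights(support, theta.p)
    for g in range(spec.m):
        logpost = logpost + composition_logpdf_matrix(
            y_row[g : g + 1], support, theta, g, spec
        )[:, 0]
    norm = logsumexp(logpost)
    if not np.isfinite(norm):
        raise ValueError(
            "all composition probabilities underflowed; the observation lies "
            "outside the support of every composition density"
        )
    probs = np.exp(logpost - norm)
    probs /= probs.sum()
    mle = support[int(np.argmax(probs))]
    mean_counts = probs @ support
    return CompositionPosterior(
        pool_index=pool_index,
        support=support,
        probs=probs,
        mle=mle.copy(),
        mean_counts=mean_counts,
        credible_set=_credible_set(support, probs),
    )


def predict_compositions(
    data: PooledDataset, theta: ParameterSet, spec: ModelSpec
) -> list[CompositionPosterior]:
    """Composition posterior for every pool of a dataset."""
    return [
        composition_posterior(data.y[i], int(data.n[i]), theta, spec, pool_index=i)
        for i in range(data.k)
    ]


def composition_accuracy(
    data: PooledDataset, theta: ParameterSet, spec: ModelSpec
) -> tuple[int, int, int]:
    """Count correctly recovered pool compositions against the ground truth.

    Returns ``(n_mle_hits, n_mean_hits, n_ci_hits)`` out of the k pools:
    the posterior-argmax composition matches exactly; the rounded posterior
    mean matches exactly; the 95% credible set contains the truth.
    """
    if data.latent_compositions is None:
        raise ValueError("dataset carries no ground-truth compositions")
    mle_hits = mean_hits = ci_hits = 0
    for post, truth in zip(predict_compositions(data, theta, spec),
                           data.latent_compositions):
        if np.array_equal(post.mle, truth):
            mle_hits += 1
        if np.array_equal(np.rint(post.mean_counts).astype(int), truth):
            mean_hits += 1
        if np.any(np.all(post.credible_set == truth, axis=1)):
            ci_hits += 1
    return mle_hits, mean_hits, ci_hits
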