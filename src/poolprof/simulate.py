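"""Synthetic pooled-expression data with known ground truth.

Each cell is assigned a population label multinomially with probabilities
``p``; its per-gene expression is drawn from that population's distribution
(lognormal, or exponential for the last EXP-LN population).  A pool's
observation is the plain sum of its cells' values per gene; the label of a
cell is drawn once and shared across genes, so the latent pool composition
is the same for every gene.  No technical measurement noise is added.

Pool-size presets mirror the two mixed regimes used in the simulation
studies: "small" cycles {1, 2, 5, 10} over the k samples and "large" cycles
{10, 15, 20, 50}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import ModelSpec, ParameterSet, PooledDataset

POOL_SIZE_PRESETS = {
    "small": (1, 2, 5, 10),
    "large": (10, 15, 20, 50),
}


@dataclass
class SimulationConfig:
    """Everything needed to generate one synthetic dataset."""

    spec: ModelSpec
    theta: ParameterSet
    pool_sizes: np.ndarray
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        self.pool_sizes = np.atleast_1d(np.asarray(self.pool_sizes, dtype=int))
        self.theta.validate(self.spec)
        if np.any(self.pool_sizes < 1):
            raise ValueError("all pool sizes must be >= 1")

    @property
    def k(self) -> int:
        return self.pool_sizes.shape[0]


def make_pool_sizes(k: int, n) -> np.ndarray:
    """Expand a pool-size request to a length-k vector.

    ``n`` may be a positive integer (homogeneous pools), a preset name
    ("small" or "large", cycled evenly over the k samples), or an explicit
    vector of length k.
    """
    if isinstance(n, str):
        if n.strip().isdigit():
            return np.full(k, int(n), dtype=int)
        cycle = POOL_SIZE_PRESETS.get(n)
        if cycle is None:
            raise ValueError(f"unknown pool-size preset {n!r}")
        return np.array([cycle[i % len(cycle)] for i in range(k)], dtype=int)
    n = np.atleast_1d(np.asarray(n, dtype=int))
    if n.size == 1:
        return np.full(k, int(n[0]), dtype=int)
    if n.size != k:
        raise ValueError(f"pool-size vector has length {n.size}, expected {k}")
    return n


def sample_single_cells(
    count: int, theta: ParameterSet, spec: ModelSpec, gene: int, rng
) -> tuple[np.ndarray, np.ndarray]:
    """Draw single-cell expression values for one gene.

    Returns ``(values, labels)`` where labels index populations 0..T-1.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    labels = rng.choice(spec.T, size=count, p=theta.p)
    values = _values_for_labels(labels, theta, spec, gene, rng)
    return values, labels


def _values_for_labels(labels, theta, spec, gene, rng):
    values = np.empty(labels.shape[0])
    sig = theta.sigma_per_lognormal_pop(spec)
    for h in range(spec.n_lognormal_pops):
        mask = labels == h
        values[mask] = rng.lognormal(theta.mu[h, gene], sig[h], size=mask.sum())
    if spec.family == "EXP-LN":
        mask = labels == spec.T - 1
        values[mask] = rng.exponential(1.0 / theta.rate[gene], size=mask.sum())
    return values


def simulate_pooled_dataset(config: SimulationConfig) -> PooledDataset:
    """Generate a pooled dataset, recording the latent pool compositions."""
    spec, theta = config.spec, config.theta
    rng = np.random.default_rng(config.rng_seed)
    k, m = config.k, spec.m
    y = np.empty((k, m))
    comps = np.zeros((k, spec.T), dtype=int)
    for i, n_i in enumerate(config.pool_sizes):
        labels = rng.choice(spec.T, size=n_i, p=theta.p)
        comps[i] = np.bincount(labels, minlength=spec.T)
        for g in range(m):
            y[i, g] = _values_for_labels(labels, theta, spec, g, rng).sum()
    return PooledDataset(
        y=y, n=config.pool_sizes.copy(), latent_compositions=comps
    )


def perturb_pool_sizes(n: np.ndarray, rng) -> np.ndarray:
    """Poisson-perturbed pool sizes, emulating uncertain cell counts.

    Each component is replaced by a Poisson draw with intensity equal to the
    component; zeros are set to one, the minimum pool size.
    """
    n = np.atleast_1d(np.asarray(n, dtype=int))
    if np.any(n < 1):
        raise ValueError("all pool sizes must be >= 1")
    drawn = rng.poisson(n)
    return np.maximum(drawn, 1)
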