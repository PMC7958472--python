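"""Pooled mixture-convolution density and the joint log-likelihood."""

import itertools
import time

import numpy as np
import pytest
from scipy import integrate, stats
from scipy.special import comb

import poolprof as pp
from poolprof.model import LOG_FLOOR, multinomial_log_weights


class TestEnumerateCompositions:
    def test_two_population_count(self):
        comps = pp.enumerate_compositions(10, 2)
        assert comps.shape == (11, 2)
        np.testing.assert_array_equal(comps[:, 0], np.arange(11))

    def test_three_population_count_brute_force(self):
        comps = pp.enumerate_compositions(5, 3)
        assert comps.shape == (21, 3)
        brute = {
            (a, b, 5 - a - b)
            for a in range(6)
            for b in range(6)
            if a + b <= 5
        }
        assert {tuple(row) for row in comps} == brute

    def test_single_cell_unit_vectors(self):
        comps = pp.enumerate_compositions(1, 3)
        np.testing.assert_array_equal(np.sort(comps.sum(axis=0)), [1, 1, 1])
        assert comps.shape == (3, 3)

    @pytest.mark.parametrize("n,T", [(5, 2), (7, 3), (4, 4)])
    def test_count_and_order(self, n, T):
        comps = pp.enumerate_compositions(n, T)
        assert comps.shape[0] == comb(n + T - 1, T - 1, exact=True)
        assert np.all(comps.sum(axis=1) == n)
        as_tuples = [tuple(r) for r in comps]
        assert as_tuples == sorted(as_tuples)


class TestMultinomialWeight:
    def test_boundary_terms(self):
        assert pp.multinomial_weight([0, 10], [0.2, 0.8]) == pytest.approx(0.8**10)
        assert pp.multinomial_weight([10, 0], [0.62, 0.38]) == pytest.approx(
            0.62**10, rel=1e-12
        )

    def test_weights_sum_to_one(self):
        comps = pp.enumerate_compositions(10, 2)
        w = np.exp(multinomial_log_weights(comps, np.array([0.2, 0.8])))
        assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_large_pool_no_overflow(self):
        comps = pp.enumerate_compositions(50, 2)
        w = np.exp(multinomial_log_weights(comps, np.array([0.3, 0.7])))
        assert w.sum() == pytest.approx(1.0, abs=1e-10)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pp.multinomial_weight([1, 2, 3], [0.5, 0.5])


class TestCompositionPdf:
    def test_pure_population_is_fw_density(self, two_pop_spec, well_separated_theta):
        fw = pp.fenton_wilkinson_combine([pp.LognormalParams(2.0, 0.2)] * 4)
        y = np.linspace(1, 60, 40)
        np.testing.assert_allclose(
            pp.composition_pdf(y, [4, 0], well_separated_theta, 0, two_pop_spec),
            pp.lognormal_pdf(y, fw),
            rtol=1e-10,
        )

    def test_pure_exponential_is_erlang(self):
        spec = pp.ModelSpec("EXP-LN", 2)
        theta = pp.ParameterSet(p=[0.3, 0.7], mu=[[1.0]], sigma=[0.2], rate=[0.5])
        y = np.linspace(0.1, 30, 30)
        np.testing.assert_allclose(
            pp.composition_pdf(y, [0, 6], theta, 0, spec),
            pp.erlang_pdf(y, 6, 0.5),
            rtol=1e-10,
        )

    def test_all_zero_composition_rejected(self, two_pop_spec, well_separated_theta):
        with pytest.raises(ValueError):
            pp.composition_pdf(1.0, [0, 0], well_separated_theta, 0, two_pop_spec)

    def test_against_monte_carlo(self, two_pop_spec, well_separated_theta):
        """Density of a (2,3) pool tracks simulated sums (KS distance < 0.02)."""
        rng = np.random.default_rng(21)
        sums = np.sort(
            rng.lognormal(2.0, 0.2, size=(10**5, 2)).sum(axis=1)
            + rng.lognormal(0.0, 0.2, size=(10**5, 3)).sum(axis=1)
        )
        grid = np.linspace(0, sums[-1] * 1.05, 4000)
        pdf = pp.composition_pdf(grid, [2, 3], well_separated_theta, 0, two_pop_spec)
        cdf = np.concatenate([[0], np.cumsum((pdf[1:] + pdf[:-1]) / 2 * np.diff(grid))])
        model_cdf = np.interp(sums, grid, cdf)
        empirical = np.arange(1, sums.size + 1) / sums.size
        assert np.max(np.abs(model_cdf - empirical)) < 0.02


class TestPooledPdf:
    def test_single_cell_is_mixture(self, two_pop_spec, narrow_theta):
        y = np.linspace(0.05, 4, 100)
        mix = 0.62 * pp.lognormal_pdf(y, pp.LognormalParams(0.47, 0.03)) + 0.38 * (
            pp.lognormal_pdf(y, pp.LognormalParams(-0.87, 0.03))
        )
        np.testing.assert_allclose(
            pp.pooled_pdf(y, 1, narrow_theta, 0, two_pop_spec), mix, rtol=1e-10
        )

    def test_normalization(self, two_pop_spec, narrow_theta):
        val, _ = integrate.quad(
            lambda y: pp.pooled_pdf(y, 10, narrow_theta, 0, two_pop_spec), 0, 50,
            limit=200,
        )
        assert val == pytest.approx(1.0, abs=1e-3)

    def test_explicit_eleven_term_sum(self, two_pop_spec, well_separated_theta):
        """The n=10 pooled density equals the explicit binomial-weighted sum."""
        y = np.array([5.0, 12.0, 30.0])
        expected = np.zeros_like(y)
        p = 0.2
        for l in range(11):
            w = comb(10, l, exact=True) * p**l * (1 - p) ** (10 - l)
            expected += w * pp.composition_pdf(
                y, [l, 10 - l], well_separated_theta, 0, two_pop_spec
            )
        np.testing.assert_allclose(
            pp.pooled_pdf(y, 10, well_separated_theta, 0, two_pop_spec),
            expected,
            rtol=1e-10,
        )

    def test_label_permutation_invariance(self):
        spec = pp.ModelSpec("rLN-LN", 2)
        theta = pp.ParameterSet(p=[0.3, 0.7], mu=[[1.0], [-0.5]], sigma=[0.4, 0.2])
        swapped = pp.ParameterSet(p=[0.7, 0.3], mu=[[-0.5], [1.0]], sigma=[0.2, 0.4])
        y = np.linspace(0.5, 20, 50)
        np.testing.assert_allclose(
            pp.pooled_pdf(y, 5, theta, 0, spec),
            pp.pooled_pdf(y, 5, swapped, 0, spec),
            rtol=1e-10,
        )

    def test_outside_support_zero(self, two_pop_spec, well_separated_theta):
        assert pp.pooled_pdf(-1.0, 5, well_separated_theta, 0, two_pop_spec) == 0.0
        assert pp.pooled_pdf(0.0, 5, well_separated_theta, 0, two_pop_spec) == 0.0

    def test_mean_is_pool_size_times_cell_mean(self, two_pop_spec, well_separated_theta):
        """Law of total expectation: pooled mean = n * single-cell mixture mean."""
        cell_mean = 0.2 * np.exp(2 + 0.02) + 0.8 * np.exp(0.02)
        val, _ = integrate.quad(
            lambda y: y * pp.pooled_pdf(y, 5, well_separated_theta, 0, two_pop_spec),
            0, 120, limit=300,
        )
        assert val == pytest.approx(5 * cell_mean, rel=0.005)


class TestLogLikelihood:
    def test_single_observation(self, two_pop_spec, well_separated_theta):
        data = pp.PooledDataset(y=[[7.0]], n=[5])
        ll = pp.log_likelihood(well_separated_theta, data, two_pop_spec)
        assert ll == pytest.approx(
            np.log(pp.pooled_pdf(7.0, 5, well_separated_theta, 0, two_pop_spec))
        )

    def test_gene_independence(self, well_separated_theta):
        spec2 = pp.ModelSpec("LN-LN", 2, m=2)
        theta2 = pp.ParameterSet(
            p=[0.2, 0.8], mu=[[2.0, 1.0], [0.0, -1.0]], sigma=[0.2]
        )
        y = np.array([[7.0, 3.0], [12.0, 5.0]])
        data2 = pp.PooledDataset(y=y, n=[5, 5])
        per_gene = 0.0
        for g in range(2):
            data_g = pp.PooledDataset(y=y[:, [g]], n=[5, 5])
            theta_g = pp.ParameterSet(
                p=[0.2, 0.8], mu=theta2.mu[:, [g]], sigma=[0.2]
            )
            per_gene += pp.log_likelihood(theta_g, data_g, pp.ModelSpec("LN-LN", 2))
        assert pp.log_likelihood(theta2, data2, spec2) == pytest.approx(per_gene)

    def test_brute_force_double_loop(self, well_separated_theta):
        spec = pp.ModelSpec("LN-LN", 2, m=3)
        theta = pp.ParameterSet(
            p=[0.2, 0.8], mu=[[2.0, 1.5, 1.0], [0.0, -0.2, -0.5]], sigma=[0.2]
        )
        rng = np.random.default_rng(9)
        cfg = pp.SimulationConfig(
            spec=spec, theta=theta, pool_sizes=pp.make_pool_sizes(50, 5), rng_seed=9
        )
        data = pp.simulate_pooled_dataset(cfg)
        brute = sum(
            max(
                np.log(pp.pooled_pdf(data.y[i, g], int(data.n[i]), theta, g, spec)),
                LOG_FLOOR,
            )
            for i, g in itertools.product(range(50), range(3))
        )
        assert pp.log_likelihood(theta, data, spec) == pytest.approx(brute, abs=1e-10)

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            pp.PooledDataset(y=[[np.nan]], n=[2])

    def test_zeros_under_lognormal_model_rejected(self, two_pop_spec, well_separated_theta):
        data = pp.PooledDataset(y=[[0.0], [1.0]], n=[5, 5])
        with pytest.raises(ValueError, match="EXP-LN"):
            data.check_support(two_pop_spec)

    def test_runtime_fifty_cell_pools(self, two_pop_spec, well_separated_theta):
        """A 50-observation likelihood with n=50 (51 compositions) is fast."""
        cfg = pp.SimulationConfig(
            spec=two_pop_spec,
            theta=well_separated_theta,
            pool_sizes=pp.make_pool_sizes(50, 50),
            rng_seed=12,
        )
        data = pp.simulate_pooled_dataset(cfg)
        start = time.perf_counter()
        pp.log_likelihood(well_separated_theta, data, two_pop_spec)
        assert time.perf_counter() - start < 1.0


class TestNormalizationAcrossFamilies:
    """Pooled densities integrate to one for every family, T and pool size."""

    @pytest.mark.parametrize("family,T", [
        ("LN-LN", 1), ("LN-LN", 2), ("LN-LN", 3),
        ("rLN-LN", 2), ("rLN-LN", 3),
        ("EXP-LN", 2), ("EXP-LN", 3),
    ])
    @pytest.mark.parametrize("n", [1, 2, 5, 10])
    def test_pooled_pdf_normalizes(self, family, T, n):
        theta = _example_theta(family, T)
        spec = pp.ModelSpec(family, T)
        upper = _pool_mean_upper_bound(theta, spec, n)
        grid = np.linspace(1e-9, upper, 1500)
        pdf = pp.pooled_pdf(grid, n, theta, 0, spec)
        total = np.trapezoid(pdf, grid)
        assert total == pytest.approx(1.0, abs=1e-3)


def _pool_mean_upper_bound(theta: pp.ParameterSet, spec: pp.ModelSpec, n: int) -> float:
    """Integration limit well past the pooled mean: n cells, each bounded by
    the largest per-population mean, plus generous tail room."""
    means = [
        pp.lognormal_moments(pp.LognormalParams(theta.mu[h, 0], s))[0]
        for h, s in enumerate(theta.sigma_per_lognormal_pop(spec))
    ]
    if theta.rate is not None:
        means.append(1.0 / theta.rate[0])
    return 3.0 * n * max(means) + 30.0


def _example_theta(family: str, T: int) -> pp.ParameterSet:
    mus = np.array([[2.0], [0.0], [-1.5]])
    p = {1: [1.0], 2: [0.3, 0.7], 3: [0.2, 0.5, 0.3]}[T]
    if family == "LN-LN":
        return pp.ParameterSet(p=p, mu=mus[:T], sigma=[0.2])
    if family == "rLN-LN":
        return pp.ParameterSet(p=p, mu=mus[:T], sigma=[0.2, 0.3, 0.4][:T])
    return pp.ParameterSet(p=p, mu=mus[: T - 1], sigma=[0.2] if T > 1 else [], rate=[0.8])
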