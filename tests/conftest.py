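import numpy as np
import pytest

import poolprof as pp


@pytest.fixture(scope="session")
def two_pop_spec():
    return pp.ModelSpec("LN-LN", 2)


@pytest.fixture(scope="session")
def well_separated_theta():
    """Two well-separated lognormal populations (minority high expressers)."""
    return pp.ParameterSet(p=[0.2, 0.8], mu=[[2.0], [0.0]], sigma=[0.2])


@pytest.fixture(scope="session")
def narrow_theta():
    """Two narrow populations, majority high expressers."""
    return pp.ParameterSet(p=[0.62, 0.38], mu=[[0.47], [-0.87]], sigma=[0.03])


@pytest.fixture(scope="session")
def five_cell_dataset(two_pop_spec, well_separated_theta):
    """100 pooled 5-cell observations from the well-separated model."""
    cfg = pp.SimulationConfig(
        spec=two_pop_spec,
        theta=well_separated_theta,
        pool_sizes=pp.make_pool_sizes(100, 5),
        rng_seed=20260930,
    )
    return pp.simulate_pooled_dataset(cfg)


@pytest.fixture(scope="session")
def five_cell_fit(five_cell_dataset, two_pop_spec):
    """Maximum-likelihood fit of the 5-cell dataset (shared across tests)."""
    return pp.fit_maximum_likelihood(
        five_cell_dataset,
        two_pop_spec,
        loops=3,
        until_convergence=True,
        rng_seed=7,
        compute_ci=False,
    )
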