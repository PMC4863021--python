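import numpy as np
import pandas as pd
import pytest

import droughtscale as ds


@pytest.fixture(scope="session")
def small_truth():
    """Generator settings small enough for fast end-to-end tests."""
    return ds.GeneratingTruth(n_sites=3, year_start=1940, year_end=2012)


@pytest.fixture(scope="session")
def small_climate(small_truth):
    return ds.simulate_climate(small_truth, seed=11)


@pytest.fixture(scope="session")
def small_bank(small_climate):
    """Index bank with a reduced SPEI grid (1..24) for unit tests."""
    return ds.build_index_bank(small_climate, spei_scales=range(1, 25),
                               spi_scales=range(1, 4))


@pytest.fixture(scope="session")
def small_truth_24(small_truth):
    """Truth whose timescales lie inside the reduced 1..24 grid."""
    t = ds.GeneratingTruth(n_sites=3, year_start=1940, year_end=2012,
                           t_hist=18, t_cont=6)
    return t


@pytest.fixture(scope="session")
def small_dataset(small_truth_24, small_bank):
    obs, record = ds.simulate_observations(
        small_truth_24, small_bank, n_wetlands=12, years_per_era=6, seed=5
    )
    return obs, record


@pytest.fixture(scope="session")
def small_mdata(small_dataset, small_bank):
    obs, _ = small_dataset
    return ds.prepare_model_data(obs, small_bank, month=8)


@pytest.fixture(scope="session")
def tiny_state(small_mdata):
    """A valid, reproducible model state for the small dataset."""
    rng = np.random.default_rng(3)
    m = small_mdata
    X = ds.build_design_matrix(m, 18, 6, 2)
    beta = np.array([-0.6, 0.6, 0.7, 0.0, -0.3, 0.0, 0.0])
    gamma = 0.2 * rng.standard_normal(m.n_wetlands)
    state = ds.ModelState(
        beta_mu=beta, beta_phi=3.0,
        gamma=gamma, epsilon=0.5 * rng.standard_normal(m.n_wetlands),
        l=X @ beta + gamma[m.wetland_idx] + 0.5 * rng.standard_normal(m.n_obs),
        m=3.0 + 0.3 * rng.standard_normal(m.n_obs),
        tau_gamma=20.0, tau_delta=0.5, tau_epsilon=0.2, tau_zeta=4.0,
        t_hist=18, t_cont=6, t_spi=2,
    )
    return state
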