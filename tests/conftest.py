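"""Shared fixtures: the default synthetic study and trained models.

The heavy objects (the integrated reference model and the fitted query
mapper) are session-scoped so the training cost is paid once and shared
by the module and acceptance tests.
"""

import numpy as np
import pytest

from scges import (
    SCGESIntegrator,
    SCGESMapper,
    align_query,
    prepare_dataset,
    simulate,
    simulate_query,
)

N_HVG_FIXTURE = 300  # HVG split for the 2000-gene default fixture


@pytest.fixture(scope="session")
def sim_default():
    """Default study: 3 batches x 5 types x 60 cells, 2000 genes, seed 0."""
    raw, truth = simulate(seed=0)
    return raw, truth


@pytest.fixture(scope="session")
def prepared(sim_default):
    raw, _ = sim_default
    return prepare_dataset(raw, n_top=N_HVG_FIXTURE)


@pytest.fixture(scope="session")
def fitted_integrator(prepared):
    return SCGESIntegrator(seed=0).fit(prepared)


@pytest.fixture(scope="session")
def query_aligned(sim_default, prepared):
    _, truth = sim_default
    raw_q, q_truth = simulate_query(truth, n_cells=300, seed=1)
    return align_query(raw_q, prepared), q_truth


@pytest.fixture(scope="session")
def fitted_mapper(fitted_integrator, prepared, query_aligned):
    query, _ = query_aligned
    mapper = SCGESMapper(integrator=fitted_integrator, seed=0)
    mapper.fit(query, prepared)
    return mapper


@pytest.fixture()
def tiny_sim():
    """A seconds-scale dataset for training-dynamics tests."""
    return simulate(
        n_batches=2, cells_per_type_per_batch=12, n_types=3,
        n_hvg_like=40, n_lvg_like=80, seed=3,
    )


@pytest.fixture()
def tiny_prepared(tiny_sim):
    raw, _ = tiny_sim
    return prepare_dataset(raw, n_top=40)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
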