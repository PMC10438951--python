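import numpy as np
import pytest
import scipy.sparse as sp

from dpsmr import (
    AdjacencyGraph,
    AgeRateTable,
    CovariateTable,
    GeneratingParameters,
    build_lattice_adjacency,
    expected_counts,
    generate_covariates,
    generate_population,
)
from dpsmr.standardize import DEFAULT_REFERENCE_RATES


@pytest.fixture(scope="session")
def two_node_graph():
    W = sp.csr_array(np.array([[0, 1], [1, 0]], dtype=np.int8))
    return AdjacencyGraph(2, W)


@pytest.fixture(scope="session")
def small_graph():
    return build_lattice_adjacency(5, 5)


@pytest.fixture(scope="session")
def small_dataset(small_graph):
    """A modest simulated dataset on a 5x5 lattice for model tests."""
    pop = generate_population(small_graph, "diffuse", seed=11)
    cov = generate_covariates(small_graph, pop, seed=12)
    rates = AgeRateTable(np.asarray(DEFAULT_REFERENCE_RATES), pop.age_bands)
    exp = expected_counts(pop, rates)
    return small_graph, pop, cov, exp


@pytest.fixture(scope="session")
def generating_params():
    return GeneratingParameters()
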