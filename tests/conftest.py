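import numpy as np
import pytest

from etnet import (CohortSpec, MIEstimatorConfig, NodeTypeScheme, PlantedEdge,
                   build_catalog, generate_cohort)


@pytest.fixture(scope="session")
def scheme():
    return NodeTypeScheme()


@pytest.fixture(scope="session")
def catalog(scheme):
    return build_catalog(scheme)


@pytest.fixture(scope="session")
def abc_catalog():
    return build_catalog(NodeTypeScheme(labels=("A", "C", "L")))


@pytest.fixture(scope="session")
def small_cohort():
    """Two-condition cohort with known planted pairs at desk scale."""
    base = [PlantedEdge(0, 1, "linear", 0.95), PlantedEdge(2, 3, "quadratic", 0.95),
            PlantedEdge(4, 5, "xor", 0.95)]
    after = [PlantedEdge(0, 1, "linear", 0.95), PlantedEdge(6, 7, "linear", 0.95)]
    spec = CohortSpec(n_molecules=12,
                      n_samples_per_condition={"OGTT0": 11, "OGTT4": 12},
                      planted_edges={"OGTT0": base, "OGTT4": after},
                      seed=11)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def fast_cfg():
    return MIEstimatorConfig(n_permutations_B=500, seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
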