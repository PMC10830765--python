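import numpy as np
import pytest

from morphgcn import (
    Parcellation,
    SimulationConfig,
    build_feature_matrix,
    simulate_cohort,
    simulate_healthy_reference,
)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_cfg():
    """A 20-region desk-scale cohort with the default atrophy structure."""
    return SimulationConfig(
        atlas_size=20,
        vertices_per_region=40,
        n_patients_per_class={"RR": 6, "PP": 6, "SP": 6, "HC": 12},
        scans_per_patient=2,
        n_ixi_subjects=30,
        seed=7,
    )


@pytest.fixture(scope="session")
def parc20():
    return Parcellation.custom(20)


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    return simulate_cohort(small_cfg)


@pytest.fixture(scope="session")
def healthy_ref(small_cfg):
    return simulate_healthy_reference(small_cfg)


@pytest.fixture(scope="session")
def small_feats(small_cohort, parc20):
    return [build_feature_matrix(s, parc20) for s in small_cohort]


@pytest.fixture(scope="session")
def healthy_feats(healthy_ref, parc20):
    return [build_feature_matrix(s, parc20) for s in healthy_ref]
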