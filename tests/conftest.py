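import numpy as np
import pytest

from scsomatic import signatures, synthetic


@pytest.fixture(scope="session")
def sbs_catalog():
    return signatures.fixture_sbs_catalog()


@pytest.fixture(scope="session")
def id_catalog():
    return signatures.fixture_id_catalog()


@pytest.fixture(scope="session")
def noiseless_config():
    """Small cohort with perfect observation: callable fraction 1, no artifacts."""
    return synthetic.SimulationConfig(
        n_individuals_per_group={"carrier": 3, "control": 3},
        cells_per_individual=(3, 4),
        germline_variants_per_individual=80,
        mean_burden_per_group={"carrier": 330.0, "control": 250.0},
        nb_dispersion=10.0,
        indel_fraction=0.08,
        clone_tree_depth=2,
        clonal_fraction=0.3,
        callable_fraction_range=(1.0, 1.0),
        artifact_rate=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def noiseless_cohort(noiseless_config):
    return synthetic.simulate_cohort(noiseless_config)


@pytest.fixture(scope="session")
def small_cohort():
    """Small noisy cohort exercising thinning, artifacts and clonality."""
    cfg = synthetic.SimulationConfig(
        n_individuals_per_group={"carrier": 2, "control": 2},
        cells_per_individual=(3, 4),
        germline_variants_per_individual=60,
        mean_burden_per_group={"carrier": 390.0, "control": 300.0},
        callable_fraction_range=(0.6, 0.9),
        artifact_rate=5.0,
        clonal_fraction=0.2,
        seed=7,
    )
    return synthetic.simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
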