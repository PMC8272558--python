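import numpy as np
import pytest

from cvrkit.blood import SubjectBlood
from cvrkit.config import load_config, protocols_from_config
from cvrkit.phantom import PhantomSpec, make_phantom, simulate_acquisitions


@pytest.fixture(scope="session")
def group_blood() -> SubjectBlood:
    """Cohort-mean blood physiology (Hct 0.43, arterial saturation)."""
    return SubjectBlood(hematocrit=0.43, hemoglobin=14.7, oxygen_saturation=0.999)


@pytest.fixture(scope="session")
def config() -> dict:
    return load_config()


@pytest.fixture(scope="session")
def protocols(config):
    return protocols_from_config(config)


@pytest.fixture(scope="session")
def tiny_spec() -> PhantomSpec:
    """Desk-scale phantom used throughout the suite."""
    return PhantomSpec(grid_shape=(24, 24, 16), voxel_size=(6.0, 6.0, 6.0),
                       n_subjects=3, seed=11)


@pytest.fixture(scope="session")
def tiny_truth(tiny_spec):
    return make_phantom(tiny_spec, 0)


@pytest.fixture(scope="session")
def noiseless_dataset(tiny_truth, protocols, tiny_spec):
    return simulate_acquisitions(tiny_truth, protocols, tiny_spec, seed=11,
                                 noiseless=True, efficiency_mode="fixed")


@pytest.fixture(scope="session")
def noisy_dataset(tiny_truth, protocols, tiny_spec):
    return simulate_acquisitions(tiny_truth, protocols, tiny_spec, seed=11,
                                 noiseless=False, efficiency_mode="fixed")
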