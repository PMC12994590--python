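import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mitrapk as mp

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def median_params() -> mp.PKParameters:
    """Reference posterior-median structural parameters."""
    return mp.REFERENCE_MEDIAN_PARAMS


@pytest.fixture(scope="session")
def default_design() -> mp.SyntheticDesign:
    return mp.SyntheticDesign(seed=7)


@pytest.fixture(scope="session")
def noisy_dataset(default_design) -> mp.ConcentrationDataset:
    """One seeded realization of the default synthetic study."""
    return mp.generate_dataset(default_design)


@pytest.fixture(scope="session")
def noisefree_dataset() -> mp.ConcentrationDataset:
    """Synthetic study in the vanishing-noise limit."""
    design = mp.SyntheticDesign(seed=1, cv_parent=1e-10, cv_metabolite=1e-10)
    return mp.generate_dataset(design)


@pytest.fixture(scope="session")
def fine_grid() -> np.ndarray:
    return np.arange(0.0, 48.0001, 0.25)
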