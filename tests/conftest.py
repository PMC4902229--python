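import numpy as np
import pytest

from nephromorph.study import simulate_study
from nephromorph.tissue import TissueParams


@pytest.fixture(scope="session")
def study_dataset():
    """One default synthetic study cohort, shared across read-only tests."""
    return simulate_study(seed=2024)


@pytest.fixture(scope="session")
def tissue_params():
    return TissueParams(
        compartment_fractions=(0.30, 0.05, 0.45, 0.10, 0.07, 0.03)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
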