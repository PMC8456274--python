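import numpy as np
import pytest

from ldims.simulate import (AcquisitionConfig, make_panel, sample_cohort)


@pytest.fixture(scope="session")
def panel():
    """Default 35-feature, 6-biomarker panel (5 up / 1 down)."""
    return make_panel(35, 6, 1.0, 5, seed=11)


@pytest.fixture(scope="session")
def cohort(panel):
    return sample_cohort(panel, 8, 8, 0.2, seed=13)


@pytest.fixture(scope="session")
def lean_acq():
    """Small grid, no chemical noise: fast Monte-Carlo configurations."""
    return AcquisitionConfig(n_points=2000, chemical_noise_density=0.0)


@pytest.fixture(scope="session")
def quiet_acq():
    """Completely noise-free acquisition."""
    return AcquisitionConfig(n_points=2000, chemical_noise_density=0.0,
                             shot_cv=0.0, shot_cv_common=0.0,
                             detector_noise_sigma=0.0)
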