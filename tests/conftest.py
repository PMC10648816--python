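import numpy as np
import pytest

from ueff.synthetic import generate_cohort, mafld_config, nafld_config


@pytest.fixture(scope="session")
def zero_noise_cohort():
    """n=90 cohort with no measurement noise: PDFF is an exact function of AC."""
    return generate_cohort(nafld_config(seed=11, noise_sd_pdff=0.0, noise_sd_bscd=0.0))


@pytest.fixture(scope="session")
def noisy_cohort():
    """Default training-like cohort (n=90, calibrated noise)."""
    return generate_cohort(nafld_config(seed=11))


@pytest.fixture(scope="session")
def external_cohort():
    """Default external-test-like cohort (n=51, leaner grade mix)."""
    return generate_cohort(mafld_config(seed=13))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)
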