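import numpy as np
import pytest

from tgios import REFERENCE_OS_MODEL, REFERENCE_TGI_MODEL
from tgios.synthetic_data import StudySpec, generate_study, sample_os_cohort


@pytest.fixture(scope="session")
def typical_params():
    return REFERENCE_TGI_MODEL.typical


@pytest.fixture(scope="session")
def one_arm_study():
    """A 150-patient single-arm study drawn from the reference TGI model."""
    spec = StudySpec(name="unit", n_patients=150, arms=(("all", 1.0, 1.0),),
                     bts_median_cm=6.99)
    return generate_study(spec, rng=np.random.default_rng(42))


@pytest.fixture(scope="session")
def os_cohort():
    """1200 survival records from the reference OS model (one arm)."""
    return sample_os_cohort(1200, rng=np.random.default_rng(2024))


@pytest.fixture(scope="session")
def two_arm_cohort():
    """600 survival records, treatment arm with doubled KDE2 (longer TTG)."""
    return sample_os_cohort(600, rng=np.random.default_rng(7), two_arm=True)


@pytest.fixture(scope="session")
def reference_os_model():
    return REFERENCE_OS_MODEL
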