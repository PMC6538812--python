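import numpy as np
import pytest

from eqdose.pk import PKParams, TreatmentCourse
from eqdose.synthetic import BASE_PK, StudyDesign


@pytest.fixture(scope="session")
def base_params() -> PKParams:
    return BASE_PK


@pytest.fixture(scope="session")
def uptake_course() -> TreatmentCourse:
    """1 uM applied at t=0, washed out at 8 h, observed through 24 h."""
    return TreatmentCourse.pulse(1000.0, 8.0, 24.0)


@pytest.fixture(scope="session")
def design() -> StudyDesign:
    return StudyDesign()


def random_pk_params(rng: np.random.Generator) -> PKParams:
    """Rates log-uniform in [1e-6, 1] /h; volume ratio log-uniform [10, 1e4]."""
    k = 10.0 ** rng.uniform(-6, 0, size=3)
    v = 10.0 ** rng.uniform(1, 4)
    return PKParams(k_EF=k[0], k_FE=k[1], k_FB=k[2], v_ratio=v)
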