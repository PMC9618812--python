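import numpy as np
import pytest

from mirpredict.synthetic_cohort import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def cohort200():
    """A mid-sized default cohort shared by read-only tests."""
    return generate_cohort(CohortSpec(n_patients=200, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
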