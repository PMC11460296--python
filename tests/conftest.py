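import numpy as np
import pytest

from pzseg.phantom import PhantomSpec, generate_cohort
from pzseg.studies import small_phantom_base, small_sampler


@pytest.fixture(scope="session")
def small_cohort():
    """Eight small-grid phantoms with gland + PZ ground truth."""
    return generate_cohort(8, small_sampler(), seed=123)


@pytest.fixture(scope="session")
def one_phantom():
    from pzseg.phantom import generate_phantom
    return generate_phantom(small_phantom_base())


@pytest.fixture
def rng():
    return np.random.default_rng(0)
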