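import numpy as np
import pytest

from fajoint.simulate import default_truth, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Default study-condition cohort, 600 children, fixed seed."""
    truth = default_truth()
    children, records = generate_cohort(truth, 600, seed=123,
                                        all_variables=True)
    return truth, children, records


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)
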