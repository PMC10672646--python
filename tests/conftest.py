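import numpy as np
import pytest
from hypothesis import settings

from organofit import CohortSpec, EstimatedParameters, KnownParameters, generate_cohort

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def known():
    return KnownParameters()


@pytest.fixture(scope="session")
def est_example():
    """A moderate, fully positive interaction-rate vector."""
    return EstimatedParameters(
        q2=0.001, q4=0.0005, q5=1e-5, q6=0.0005, delta_CAF=0.1,
        q7=0.001, q8=1e-5, q9=1e-5,
    )


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Four patients sharing one sampled truth, densely measured, no noise."""
    spec = CohortSpec(
        n_patients=4,
        measurement_days=tuple(np.arange(0.0, 21.0001, 0.125)),
        noise_cv=0.0,
        seed=1,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def sparse_cohort():
    """Four patients measured on the study's days 7/14/21, no noise."""
    spec = CohortSpec(
        n_patients=4, measurement_days=(7.0, 14.0, 21.0), noise_cv=0.0, seed=7
    )
    return generate_cohort(spec)
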