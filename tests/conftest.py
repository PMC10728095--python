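import numpy as np
import pytest
from hypothesis import settings

from ctldyn.cohort import CohortSpec, run_cohort, sample_cohort
from ctldyn.parameters import PARAMETER_NAMES, ParameterSet

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def baseline():
    return ParameterSet.baseline()


@pytest.fixture(scope="session")
def small_cohort_result():
    """A 300-mouse cohort run under both modes (shared across tests)."""
    spec = CohortSpec(n=300, seed=11)
    return run_cohort(sample_cohort(spec), spec=spec)


def random_parameter_sets(n, seed):
    """Uniform draws over the published ranges, as ParameterSet objects."""
    draws = sample_cohort(CohortSpec(n=n, seed=seed))
    return [ParameterSet.from_dict({k: float(row[k])
                                    for k in PARAMETER_NAMES})
            for _, row in draws.iterrows()]
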