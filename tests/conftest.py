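import numpy as np
import pytest
from hypothesis import settings

from mctmm.cohort import CohortDesign, generate_cohort
from mctmm.data import pack
from mctmm.model_core import CovariateSpec, PopulationParams

settings.register_profile("suite", deadline=None, max_examples=25,
                          derandomize=True)
settings.load_profile("suite")

#: Seed convention used throughout the suite.
SEED = 12345


@pytest.fixture(scope="session")
def reference_params() -> PopulationParams:
    """The published final-model estimates, used as simulation truth."""
    return PopulationParams.reference()


@pytest.fixture(scope="session")
def final_spec() -> CovariateSpec:
    return CovariateSpec.final()


@pytest.fixture(scope="session")
def small_cohort(reference_params, final_spec):
    """20-subject synthetic cohort (default design rescaled)."""
    return generate_cohort(CohortDesign.scaled(20), reference_params,
                           final_spec, np.random.default_rng(SEED))


@pytest.fixture(scope="session")
def small_packed(small_cohort):
    return pack(small_cohort)


@pytest.fixture(scope="session")
def full_cohort(reference_params, final_spec):
    """150-subject synthetic cohort with the default design."""
    return generate_cohort(CohortDesign(), reference_params, final_spec,
                           np.random.default_rng(SEED))
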