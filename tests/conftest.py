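import numpy as np
import pytest

from polypk import PopulationModel, StudyDesign, generate_cohort
from polypk.estimation import FitSettings


@pytest.fixture(scope="session")
def final_model() -> PopulationModel:
    """The published final population model (package defaults)."""
    return PopulationModel()


@pytest.fixture(scope="session")
def study_cohort(final_model):
    """One deterministic 26-subject mixed rich/sparse cohort."""
    return generate_cohort(StudyDesign(), final_model, np.random.default_rng(42))


@pytest.fixture(scope="session")
def fast_settings() -> FitSettings:
    """Estimation settings for test-sized problems (no SEs, no polish)."""
    return FitSettings(compute_se=False, polish=False)


@pytest.fixture(scope="session")
def study_fit(study_cohort, fast_settings):
    """The FOCE fit of the session cohort, shared across diagnostic tests."""
    from polypk.estimation import fit

    return fit(study_cohort, settings=fast_settings)
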