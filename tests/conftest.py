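import pytest
from hypothesis import settings, HealthCheck

from ferrodyn import (DiseaseParameters, DrugEffectParameters, InfusionRegimen,
                      DEFAULT_PK)
from ferrodyn.cohort import CohortSpec, simulate_cohort, subjects_from_table
from ferrodyn.estimation import PopulationModel

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def disease():
    return DiseaseParameters()


@pytest.fixture(scope="session")
def drug():
    return DrugEffectParameters()


@pytest.fixture(scope="session")
def reference_regimen():
    """The virtual reference patient: 45 kg, 45 mg/kg/day, 5 days/week."""
    return InfusionRegimen(dose_per_kg=45.0, body_weight=45.0)


@pytest.fixture(scope="session")
def pk():
    return DEFAULT_PK


@pytest.fixture(scope="session")
def truth():
    """Generating population model at the reference parameter estimates."""
    return PopulationModel()


@pytest.fixture(scope="session")
def small_cohort(truth):
    """A reduced 8-subject cohort with short follow-up for fast fitting tests."""
    spec = CohortSpec(n_subjects=8, max_followup_years=4.0, p_complete=0.8)
    table, subjects = simulate_cohort(spec, truth, seed=123)
    return table, subjects, subjects_from_table(table)


@pytest.fixture(scope="session")
def study_cohort(truth):
    """One full-size 27-subject cohort at the study design."""
    table, subjects = simulate_cohort(CohortSpec(), truth, seed=2024)
    return table, subjects, subjects_from_table(table)
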