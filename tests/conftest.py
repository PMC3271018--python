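import pytest

from neurocausal.design import generate_event_design
from neurocausal.hrf import build_hrf_basis
from neurocausal.simulate import (CohortSpec, GroupSpec, generate_cohort,
                                  null_cohort_spec)


@pytest.fixture(scope="session")
def design():
    return generate_event_design(n_trials=20, seed=0)


@pytest.fixture(scope="session")
def basis():
    return build_hrf_basis(2.0)


@pytest.fixture(scope="session")
def small_cohort():
    """Single-group hub cohort kept small for unit tests."""
    spec = CohortSpec(groups={"adult": GroupSpec(n_subjects=5)},
                      n_timepoints=220, seed=42)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def two_group_cohort():
    """Two-group cohort with the weakened hub->parietal edge."""
    spec = CohortSpec(seed=7)
    spec.groups["adult"].n_subjects = 6
    spec.groups["child"].n_subjects = 6
    spec.groups["adult"].structure_coupled = True
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def null_cohort():
    return generate_cohort(null_cohort_spec(seed=5, n_subjects=6))

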