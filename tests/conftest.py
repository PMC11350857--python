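import numpy as np
import pytest

from ceftazpk import (
    CohortConfig,
    PopulationParameters,
    generate_cohort,
    generate_tdm_dataset,
)


@pytest.fixture(scope="session")
def pop():
    """Published population parameters (final-model estimates)."""
    return PopulationParameters()


@pytest.fixture(scope="session")
def typical():
    from ceftazpk import IndividualParameters

    return IndividualParameters(CL=4.45, V=88.0)


@pytest.fixture(scope="session")
def small_dataset(pop):
    """A 20-subject synthetic TDM dataset at the study design."""
    cfg = CohortConfig(n_subjects=20, seed=11)
    return generate_tdm_dataset(generate_cohort(cfg), pop, cfg)


@pytest.fixture(scope="session")
def small_fit(small_dataset, pop):
    """A single-start fit of the 20-subject dataset, shared across tests."""
    from ceftazpk import FitSettings, fit_population

    return fit_population(small_dataset, init=pop, settings=FitSettings(n_starts=1))


@pytest.fixture(scope="session")
def study_dataset(pop):
    """A full-size (86-subject) synthetic TDM dataset."""
    cfg = CohortConfig(n_subjects=86, seed=7)
    return generate_tdm_dataset(generate_cohort(cfg), pop, cfg)
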