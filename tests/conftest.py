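import pytest

from ptsdce import CohortConfig, MarkovSpec, StateValueSet, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(CohortConfig(seed=7))


@pytest.fixture(scope="session")
def large_cohort():
    # 20k per arm keeps the Monte-Carlo error of proportion checks well
    # inside the +/-0.02 bands used against it
    return generate_cohort(
        CohortConfig(n_treatment=20000, n_control=20000, seed=11)
    )


@pytest.fixture
def markov_spec():
    return MarkovSpec()


@pytest.fixture
def state_values():
    return StateValueSet()
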