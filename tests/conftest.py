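import pytest

import crcscreen as cs


@pytest.fixture(scope="session")
def defaults():
    return cs.default_parameters()


@pytest.fixture(scope="session")
def incidence():
    return cs.default_incidence()


@pytest.fixture(scope="session")
def life_table():
    return cs.default_life_table()


@pytest.fixture(scope="session")
def zero_mortality_life():
    """Life table with no other-cause mortality (closing age 110)."""
    return cs.gen_life_table(0.0, 0.0, 0.0)


@pytest.fixture(scope="session")
def baseline_results(defaults, incidence, life_table):
    """All four strategies run once on the shared synthetic inputs."""
    return {
        name: cs.run_cohort(name, defaults, incidence, life_table)
        for name in cs.STRATEGY_NAMES
    }
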