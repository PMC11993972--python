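import numpy as np
import pytest

import medflysit as m


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def micro_config():
    """~100 adult females; fast, noisy."""
    return m.make_fixture_scenario("micro")


@pytest.fixture(scope="session")
def desk_config():
    """~5,000 adult females; the scale used for behavioural checks."""
    return m.make_fixture_scenario("desk")


@pytest.fixture(scope="session")
def desk_calibration(desk_config):
    return m.calibrate_equilibrium(desk_config, seed=123)


@pytest.fixture(scope="session")
def desk_calibrated(desk_config, desk_calibration):
    return desk_config.replace(expected_larvae=desk_calibration.expected_larvae)


def adult_population(config, n_females=0, state=m.MatingState.FIRST_FERTILE,
                     female_age=None, n_males=0, male_age=None):
    """Population with the given adults only (default ages: past the first
    adult week for females, emergence age for males)."""
    pop = m.Population.empty(config)
    ea = config.adult_emergence_age
    if female_age is None:
        female_age = ea + 1
    if male_age is None:
        male_age = ea
    if n_females:
        pop.females[female_age, m.STATE_INDEX[state]] = n_females
    if n_males:
        pop.males[male_age] = n_males
    return pop
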