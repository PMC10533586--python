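import pytest

from pinetrace.simulate import default_scenario, simulate_campaign


@pytest.fixture(scope="session")
def default_campaign():
    """One noisy campaign at the study's default conditions (seed 7)."""
    scenario = default_scenario(seed=7)
    table, truth = simulate_campaign(scenario)
    return scenario, table, truth


@pytest.fixture(scope="session")
def noiseless_campaign():
    """Zero measurement noise; ground truth is recoverable exactly."""
    scenario = default_scenario(seed=11).zero_noise()
    table, truth = simulate_campaign(scenario)
    return scenario, table, truth
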