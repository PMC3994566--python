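import pytest
from hypothesis import settings

from pilotgo import effect_estimate

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")
from pilotgo.datasets import leg_ulcer_definitive, leg_ulcer_pilot, leg_ulcer_priors


@pytest.fixture(scope="session")
def pilot_trial():
    return leg_ulcer_pilot()


@pytest.fixture(scope="session")
def pilot_effect(pilot_trial):
    return effect_estimate(pilot_trial)


@pytest.fixture(scope="session")
def definitive_trial():
    return leg_ulcer_definitive()


@pytest.fixture(scope="session")
def priors():
    return {p.label: p for p in leg_ulcer_priors()}
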