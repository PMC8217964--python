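import pytest

from oppmcda import default_efor_registry, pilot_workshop_votes

# swing increments elicited in the pilot workshop, as fractions (rank i over rank i+1)
PILOT_INCREMENTS = (0.145, 0.168, 0.205, 0.303, 0.232, 0.161, 0.0, 0.195)
# published final weights after 1-decimal display rounding, rank order
PILOT_WEIGHTS_PCT = (19.8, 17.3, 14.8, 12.3, 9.4, 7.7, 6.6, 6.6, 5.5)


@pytest.fixture(scope="session")
def registry():
    return default_efor_registry()


@pytest.fixture(scope="session")
def pilot_votes():
    return pilot_workshop_votes(seed=0)
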