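import numpy as np
import pytest

from respirox.simulate import AnimalModel, ChamberSpec, TrialProtocol, simulate_trial
from respirox.units import WaterConditions


@pytest.fixture(scope="session")
def cond32():
    return WaterConditions(temperature_c=26.0, salinity_psu=32.0)


@pytest.fixture(scope="session")
def cond6():
    return WaterConditions(temperature_c=26.0, salinity_psu=6.0)


@pytest.fixture(scope="session")
def chamber40():
    return ChamberSpec(volume=40.0, microbial_rate=0.0)


@pytest.fixture(scope="session")
def hypoxia_protocol():
    return TrialProtocol(trial_type="hypoxia", start_po2=11.7)


@pytest.fixture(scope="session")
def noiseless_hypoxia(cond6, chamber40):
    """One noiseless hypoxia trial with EPOC-decaying demand."""
    animal = AnimalModel(mass=594.1, smr=3.0, mmr0=9.0, alpha_true=0.68)
    protocol = TrialProtocol(trial_type="hypoxia", start_po2=11.7, noise_sd=0.0)
    return simulate_trial(animal, protocol, chamber40, cond6, seed=0)


@pytest.fixture(scope="session")
def noisy_hypoxia(cond6, chamber40, hypoxia_protocol):
    """One default-noise hypoxia trial (alpha_true = 0.68)."""
    animal = AnimalModel(mass=594.1, smr=3.0, mmr0=9.0, alpha_true=0.68)
    return simulate_trial(animal, hypoxia_protocol, chamber40, cond6, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
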