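import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from drgquant import ImagingProtocol
from drgquant.synth import SimConfig, generate_imaging_dataset


@pytest.fixture(scope="session")
def protocol() -> ImagingProtocol:
    """Default acquisition protocol: 0.7 Hz, 30 baseline frames, two
    stimulus epochs of 10 pre / 10 stim / 10 post frames."""
    return ImagingProtocol()


@pytest.fixture(scope="session")
def small_protocol() -> ImagingProtocol:
    """A small field for stack-rendering tests."""
    return ImagingProtocol(field_size_um=192.0, stimulus_labels=("30g",))


@pytest.fixture(scope="session")
def noiseless_session(protocol):
    """300 noiseless neurons, 2 stimuli, responder probability 0.1."""
    cfg = SimConfig(n_neurons=300, responder_probability=0.1, noise_sd=0.0, seed=11)
    return generate_imaging_dataset(cfg, protocol)
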