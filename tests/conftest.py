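"""Shared fixtures: montage, lead field, small datasets, a tiny trained decoder."""
import pytest

from eegxai import simulate as sim
from eegxai.decoder import EEGDecoder
from eegxai.head_model import build_default_montage


@pytest.fixture(scope="session")
def montage():
    return build_default_montage()


@pytest.fixture(scope="session")
def temporal_leadfield(montage):
    return sim.signal_leadfield("temporal", montage)


@pytest.fixture(scope="session")
def sensorimotor_leadfield(montage):
    return sim.signal_leadfield("spectral", montage)


@pytest.fixture(scope="session")
def small_temporal():
    """High-SNR temporal condition, 10 trials/class."""
    return sim.generate_condition("temporal", -3.5, 10, seed=11)


@pytest.fixture(scope="session")
def tiny_decoder(small_temporal):
    """A briefly trained decoder — not accurate, but a real ReLU CNN."""
    epochs, _ = small_temporal
    dec = EEGDecoder(max_epochs=2, patience=0, seed=3, batch_size=16)
    dec.fit(epochs.data, epochs.labels)
    return dec
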