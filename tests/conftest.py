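import numpy as np
import pytest

from ssvep_uac import StimulusVocabulary, SynthConfig


@pytest.fixture(scope="session")
def ucsd_vocab():
    return StimulusVocabulary.ucsd12()


@pytest.fixture(scope="session")
def bench_vocab():
    return StimulusVocabulary.benchmark40()


@pytest.fixture(scope="session")
def small_vocab():
    """Six well-separated targets for fast end-to-end tests."""
    return StimulusVocabulary([8.0, 9.0, 10.0, 11.0, 12.0, 13.0])


@pytest.fixture
def small_synth(small_vocab):
    """Fast generator conditions: 6 targets, 4 channels, 0.5 s epochs."""
    return SynthConfig(
        vocabulary=small_vocab,
        sampling_rate=250.0,
        epoch_length=0.5,
        n_channels=4,
        snr_db=-5.0,
        seed=1234,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
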