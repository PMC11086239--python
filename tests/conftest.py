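import numpy as np
import pytest

from fecgx.synthetic import SynthConfig, synth_aecg, synth_single_ecg, FETAL_MORPHOLOGY


@pytest.fixture(scope="session")
def clean_fetal_record():
    """60 s clean fetal ECG at 140 bpm, 500 Hz, no jitter."""
    return synth_single_ecg(140.0, 60.0, 500.0, FETAL_MORPHOLOGY, 0.0, seed=7)


@pytest.fixture(scope="session")
def aecg_pair():
    """Default-condition synthetic (AECG, clean FECG) pair, 1 channel."""
    return synth_aecg(SynthConfig(seed=42, n_channels=1))


@pytest.fixture(scope="session")
def aecg_pair_4ch():
    return synth_aecg(SynthConfig(seed=43))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
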