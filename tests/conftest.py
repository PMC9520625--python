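import numpy as np
import pytest

from sonocrack import (
    EchoModelParams, EncoderConfig, VMDConfig, generate_signal, vmd_decompose,
)


@pytest.fixture(scope="session")
def intact_record():
    """One noiseless-ish intact synthetic A-scan (default parameters)."""
    return generate_signal(1, EchoModelParams(), seed=1)


@pytest.fixture(scope="session")
def default_vmd(intact_record):
    """The M=3 decomposition of the intact record under defaults."""
    return vmd_decompose(intact_record.amplitudes, VMDConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def encoder_config():
    return EncoderConfig()
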