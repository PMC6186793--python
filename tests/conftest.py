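import numpy as np
import pytest

from ncrpi import synthesize_dataset, synthesize_pssms


@pytest.fixture(scope="session")
def small_signal_dataset():
    """60-pair planted-signal dataset shared by fast end-to-end tests."""
    return synthesize_dataset(
        30, 30, protein_len_range=(40, 80), rna_len_range=(50, 120),
        signal_strength=1.0, seed=7,
    )


@pytest.fixture(scope="session")
def small_pssms(small_signal_dataset):
    return synthesize_pssms(small_signal_dataset.proteins, noise_sd=0.3, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
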