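import numpy as np
import pytest

from nirscast import DatasetSpec, Signal1D, generate_dataset

FS = 8.138


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230685)


@pytest.fixture(scope="session")
def small_dataset():
    """Ten 640-s records (5 with a response), shared across read-only tests."""
    return generate_dataset(DatasetSpec(n_records=10, master_seed=42))


def make_signal(samples, fs=FS, label=""):
    return Signal1D(np.asarray(samples, dtype=float), fs, label)
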