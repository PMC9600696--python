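import numpy as np
import pytest

from eegmotif import SynthConfig, generate_records


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def small_dataset():
    """24 records (2 classes x 4 subjects x 3 epochs), full 14 x 512 shape."""
    cfg = SynthConfig(n_subjects_per_class=4, records_per_subject=3, seed=7)
    return generate_records(cfg)


@pytest.fixture(scope="session")
def synth_default():
    """The default study-scale dataset: 200 records from 20 subjects."""
    return generate_records(SynthConfig(seed=1))
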