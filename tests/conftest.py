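import numpy as np
import pytest

import optxfe as ox


@pytest.fixture
def toy_matrix():
    """3 samples x 2 channels toy signal with hand-derivable identities."""
    return np.array([[3.0, 1.0], [2.0, 5.0], [4.0, 4.0]])


@pytest.fixture(scope="session")
def strong_dataset():
    """Small, clearly separable dataset with subject structure."""
    cfg = ox.SimConfig(
        n_subjects_per_class=6, segments_per_subject=4, n_channels=8,
        n_samples=500, burst_rate=3.0, subject_gain_sd=0.3, noise_sd=1.0, seed=1,
    )
    return cfg, ox.generate_dataset(cfg)


@pytest.fixture(scope="session")
def strong_model(strong_dataset):
    _, segments = strong_dataset
    return ox.OpTXfe.from_segments(segments)


@pytest.fixture(scope="session")
def reference_symbols():
    return ox.parse_dlob_string(ox.load_reference_sentence())
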