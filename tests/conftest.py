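import numpy as np
import pytest

import ses_microstates as ms


@pytest.fixture(scope="session")
def atlas():
    return ms.canonical_atlas()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def ground_truth():
    return ms.default_ground_truth(seed=7, snr=1.0)


@pytest.fixture(scope="session")
def short_subject(ground_truth):
    """One 60-s synthetic subject: ground-truth stream plus noisy recording."""
    seg = ms.sample_label_stream(ground_truth, duration_s=60, fs=1000,
                                 seed=11, epoch_s=2.0)
    rec = ms.render_eeg(seg, ground_truth, fs=1000, seed=12)
    return seg, rec


def random_maps(rng, n, n_channels=8):
    """Average-referenced random topographies with nonzero variance."""
    maps = rng.normal(size=(n, n_channels))
    return maps - maps.mean(axis=1, keepdims=True)
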