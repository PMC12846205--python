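import numpy as np
import pytest

from eeg_augkit.segment import EEGSegment


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def segment(rng):
    """A two-channel 10-s segment at 100 Hz with unequal channel scales."""
    data = rng.standard_normal((2, 1000))
    data[1] *= 3.0
    return EEGSegment(data=data, fs=100.0, label=1,
                      channel_names=["a", "b"], source_id="fixture-seg")


def make_separable_dataset(n=200, n_samples=1500, offset=0.5, seed=0):
    """Two-class task separable by mean amplitude (class 1 is offset upward)."""
    from eeg_augkit.pipeline import Dataset

    r = np.random.default_rng(seed)
    X = r.standard_normal((n, 2, n_samples)).astype(np.float32)
    y = np.tile([0, 1], n // 2)
    X[y == 1] += offset
    return Dataset(X=X, y=y, ids=[f"s{i:04d}" for i in range(n)], fs=100.0)
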