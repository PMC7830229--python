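import numpy as np
import pytest

from dtcn.data_prep import DataVector, MiniBatch, TimeSeriesRecord


def batch_from_arrays(X, counts, t0=0, step=1):
    """Assemble a MiniBatch from a feature matrix and a counts matrix."""
    X = np.asarray(X, dtype=float)
    counts = np.asarray(counts)
    return MiniBatch(
        tuple(
            DataVector(X[i], counts[i], t0 + i * step)
            for i in range(X.shape[0])
        )
    )


@pytest.fixture
def small_record():
    """Deterministic 3-channel record with a mid-series label switch."""
    rng = np.random.default_rng(123)
    values = rng.normal(size=(60, 3))
    labels = np.array([0] * 30 + [1] * 30)
    return TimeSeriesRecord(values, labels, n_classes=2)


@pytest.fixture
def random_batch():
    """A 10-instance batch with tie-free label counts, for training tests."""
    rng = np.random.default_rng(42)
    X = rng.normal(size=(10, 6))
    counts = np.zeros((10, 2), dtype=int)
    counts[:5, 0] = 4
    counts[:5, 1] = 1
    counts[5:, 1] = 4
    counts[5:, 0] = 1
    return batch_from_arrays(X, counts)
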