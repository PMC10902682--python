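import numpy as np
import pytest

from ts2inet.signal_io import RawRecord, SignalDataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_dataset(rng, n_classes=3, per_class=4, min_len=5, max_len=40):
    """Small random ragged dataset for I/O round-trip checks."""
    records = []
    for c in range(n_classes):
        for r in range(per_class):
            n = int(rng.integers(min_len, max_len + 1))
            records.append(RawRecord(f"c{c}r{r}", rng.normal(size=n), f"class{c}"))
    return SignalDataset(records)


@pytest.fixture
def small_dataset(rng):
    return random_dataset(rng)
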