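import numpy as np
import pytest

from prvarr import synthetic
from prvarr.types import PRVSegment


@pytest.fixture(scope="session")
def dataset():
    """Full-scale synthetic dataset: 400 segments per rhythm class."""
    return synthetic.make_dataset(n_segments_per_class=400, seed=7)


@pytest.fixture(scope="session")
def small_dataset():
    """Quick dataset for schema-level tests: 40 segments per class."""
    return synthetic.make_dataset(n_segments_per_class=40, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_segment(prv=None, ppi=None, apm=None, label=None):
    """Build a consistent PRVSegment from whichever series is given."""
    if prv is None and ppi is not None:
        ppi = np.asarray(ppi, dtype=float)
        prv = 60000.0 / ppi
    elif prv is not None:
        prv = np.asarray(prv, dtype=float)
        ppi = 60000.0 / prv
    else:
        raise ValueError("give prv or ppi")
    if apm is None:
        apm = np.ones_like(prv)
    return PRVSegment(prv=prv, ppi=ppi, apm=np.asarray(apm, float), label=label)
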