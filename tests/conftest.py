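import numpy as np
import pytest

from vbpbb import RegularSeries


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_series(values, **kw):
    return RegularSeries(np.asarray(values, dtype=float), **kw)
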