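import numpy as np
import pytest

from pyroclim import ProxySeries


@pytest.fixture
def series_factory():
    """Build a ProxySeries from values, years starting at 0 by default."""
    def make(values, start=0, resolution=1.0, label="test"):
        values = np.asarray(values, dtype=float)
        return ProxySeries(time=np.arange(start, start + len(values), dtype=float),
                           value=values, resolution=resolution, label=label)
    return make


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
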