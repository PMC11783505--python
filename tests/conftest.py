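import numpy as np
import pandas as pd
import pytest

from eventconn.events import BoundaryVector
from eventconn.timeseries import RoiTimeSeries


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def boundary_vector(rng):
    """A non-degenerate indicator over 600 volumes (TR 2.47 s)."""
    ind = np.zeros(600, dtype=int)
    ind[rng.choice(600, size=60, replace=False)] = 1
    return BoundaryVector(ind, tr_s=2.47)


@pytest.fixture
def random_timeseries(rng):
    data = pd.DataFrame(
        rng.standard_normal((193, 5)), columns=[f"roi{i}" for i in range(5)]
    )
    return RoiTimeSeries(data, tr_s=2.47, subject_id="sub-0001")
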