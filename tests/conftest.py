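from datetime import datetime

import numpy as np
import pytest

from hybridhmm import ObservationMatrix, sample_home, small_home


@pytest.fixture
def t0():
    return datetime(2012, 1, 2)


@pytest.fixture
def obs_factory(t0):
    """Build an ObservationMatrix from a plain column dict or array."""

    def make(values, sensor_ids=None, dt=60.0):
        values = np.asarray(values)
        if sensor_ids is None:
            sensor_ids = [f"s{i}" for i in range(values.shape[1])]
        return ObservationMatrix(values, sensor_ids, t0, dt)

    return make


@pytest.fixture(scope="session")
def small_sim():
    """A 3-day simulated home at coarse slices, shared across tests."""
    return sample_home(small_home(n_days=3, dt=120), seed=7)
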