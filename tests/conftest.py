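import numpy as np
import pandas as pd
import pytest

from glucast.io import GlucoseSeries

T0 = pd.Timestamp("2024-01-01 00:00:00")


def make_series(values, mask=None, t0=T0, patient_id="test"):
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = ~np.isnan(values)
    return GlucoseSeries(patient_id, t0, values, np.asarray(mask, dtype=bool))


def cubic_trace(n=200):
    """Samples of a cubic polynomial staying inside the glucose range;
    not-a-knot cubic splines must reproduce it exactly."""
    x = np.arange(n, dtype=float)
    c = x - n / 2
    return 180.0 + 0.3 * c + 0.004 * c**2 - 0.0001 * c**3


@pytest.fixture
def constant_series():
    return make_series(np.full(120, 130.0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
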