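import numpy as np
import pytest

from mnscreen.phenocurves import WellSeries


def make_series(obs, well_id="W1", donor_id="D1", endpoint_day=None, **kw):
    """Shorthand for a WellSeries from a {day: length} dict (None = failed)."""
    return WellSeries(
        well_id=well_id,
        donor_id=donor_id,
        observations=dict(obs),
        endpoint_day=endpoint_day,
        **kw,
    )


@pytest.fixture
def day_grid():
    return list(range(22, 61))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
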