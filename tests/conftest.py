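import logging

import numpy as np
import pandas as pd
import pytest

from sdindex import DailySeries


@pytest.fixture(autouse=True)
def _quiet_pipeline_logs(caplog):
    # pipeline warnings about sparse calendar days are expected in many tests
    logging.getLogger("sdindex.pipeline").setLevel(logging.ERROR)
    yield


@pytest.fixture
def daily_index_1950_2021():
    return pd.date_range("1950-01-01", "2021-12-31", freq="D")


@pytest.fixture
def complete_series_1950_2021(daily_index_1950_2021):
    rng = np.random.default_rng(11)
    values = rng.gamma(2.0, 3.0, len(daily_index_1950_2021))
    return DailySeries(daily_index_1950_2021, values, "mm")


def make_series(values, start="2000-01-01", units=""):
    idx = pd.date_range(start, periods=len(values), freq="D")
    return DailySeries(idx, np.asarray(values, dtype=float), units)
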