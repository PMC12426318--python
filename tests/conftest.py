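import numpy as np
import pandas as pd
import pytest

import zerolux as zl


@pytest.fixture
def three_row_csv(tmp_path):
    path = tmp_path / "tiny.csv"
    path.write_text(
        "Datetime,MEDI,Id\n"
        "2024-05-06T00:00:00,0,participant\n"
        "2024-05-06T00:05:00,0,participant\n"
        "2024-05-06T00:10:00,1,participant\n")
    return path


@pytest.fixture
def hourly_day():
    """24 hourly samples over one day, alternating zero/positive at night."""
    ts = pd.date_range("2024-05-06", periods=24, freq="1h")
    lux = np.where((ts.hour >= 6) & (ts.hour < 18), 100.0, 0.0)
    return zl.LightTimeSeries(ts, lux, "participant", 3600)


@pytest.fixture(scope="session")
def synthetic_week():
    """One seeded week of combined participant + environment data."""
    return zl.simulate_week(zl.SimConfig(seed=5))


@pytest.fixture(scope="session")
def comparison(synthetic_week):
    """The four-model comparison table on the shared synthetic week."""
    return zl.compare_models(synthetic_week)
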