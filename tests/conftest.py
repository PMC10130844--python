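import numpy as np
import pandas as pd
import pytest

import heatlag as hl


@pytest.fixture(scope="session")
def small_study():
    """A compact two-year synthetic study (single age group, ~5k visits)."""
    cfg = hl.SimulationConfig(years=(2005, 2006), baseline_daily={"18-25": 27.0})
    return hl.simulate_study(cfg, seed=42)


@pytest.fixture(scope="session")
def small_run_config():
    return hl.RunConfig(years=(2005, 2006))


@pytest.fixture()
def flat_series():
    """A constant 70°F series covering May 20 – Aug 31, 2005."""
    idx = pd.date_range("2005-05-20", "2005-08-31", freq="D")
    frame = pd.DataFrame(
        {"tmin_f": 70.0, "tmean_f": 79.0, "rh_pct": 60.0}, index=idx
    )
    return hl.CityTemperatureSeries(frame)


@pytest.fixture()
def varying_series():
    """A smooth deterministic series covering May 20 – Aug 31, 2005."""
    idx = pd.date_range("2005-05-20", "2005-08-31", freq="D")
    t = 68.0 + 6.0 * np.sin(np.arange(len(idx)) / 5.0)
    frame = pd.DataFrame(
        {"tmin_f": t, "tmean_f": t + 9.0, "rh_pct": 60.0}, index=idx
    )
    return hl.CityTemperatureSeries(frame)
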