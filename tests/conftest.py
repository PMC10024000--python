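import numpy as np
import pandas as pd
import pytest

from aqfusion import SynthConfig
from aqfusion.gapfill import RegularSeries


@pytest.fixture
def small_cfg() -> SynthConfig:
    """One month, five stations: cheap enough for every generator."""
    return SynthConfig(
        n_stations=5,
        period_start="2016-01-01",
        period_end="2016-01-31",
        rng_seed=7,
    )


@pytest.fixture
def hourly_series() -> RegularSeries:
    """Ten days of hourly data with a few interior gaps."""
    rng = np.random.default_rng(11)
    values = 20.0 + rng.normal(0.0, 3.0, 240)
    values[[5, 6, 50, 51, 52, 120]] = np.nan
    return RegularSeries(start=pd.Timestamp("2016-03-01"), step="1h", values=values)
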