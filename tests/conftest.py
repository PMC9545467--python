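import numpy as np
import pandas as pd
import pytest

from ventiscan import (
    DetectionConfig,
    FLUXNET2015_MAP,
    FluxSeries,
    SyntheticScenario,
    generate,
)


@pytest.fixture(scope="session")
def default_scenario():
    return SyntheticScenario(seed=42)


@pytest.fixture(scope="session")
def default_site(default_scenario):
    """Generated default dryland site-year plus its ground truth."""
    return generate(default_scenario)


@pytest.fixture(scope="session")
def null_site():
    """Same site with the ventilation mechanism switched off."""
    return generate(SyntheticScenario(seed=42, ve_gain=0.0))


@pytest.fixture
def cfg():
    return DetectionConfig()


def make_series(frame: pd.DataFrame, site_id: str = "TEST") -> FluxSeries:
    """Wrap a canonical-column DataFrame (DatetimeIndex) as a FluxSeries."""
    frame = frame.copy()
    frame.index.name = "TIMESTAMP_START"
    return FluxSeries(site_id=site_id, data=frame, variable_provenance=FLUXNET2015_MAP)


def year_frame(year=2013, columns=("FC", "USTAR", "SW_IN"), fill=np.nan):
    """A full-year half-hourly frame with the given canonical columns."""
    n = (366 if pd.Timestamp(year=year, month=1, day=1).is_leap_year else 365) * 48
    idx = pd.date_range(f"{year}-01-01", periods=n, freq="30min")
    return pd.DataFrame({c: np.full(n, fill) for c in columns}, index=idx)
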