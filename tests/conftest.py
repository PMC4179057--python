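import pandas as pd
import pytest

from nightwatch.events import SensorEvent


@pytest.fixture
def ts0():
    """A 10 p.m. night boundary."""
    return pd.Timestamp("2014-01-06 22:00:00", tz="UTC")


@pytest.fixture
def make_event(ts0):
    """Event factory: symbol plus offset in seconds from the night start."""

    def _make(symbol: str, offset_s: float, night_id: str = "2014-01-06"):
        return SensorEvent(
            ts=ts0 + pd.to_timedelta(offset_s, unit="s"),
            symbol=symbol,
            night_id=night_id,
        )

    return _make
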