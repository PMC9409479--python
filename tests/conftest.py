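import datetime as dt

import pytest
from hypothesis import HealthCheck, settings

from seedwasp.phenology import DailyWeather

settings.register_profile(
    "default", derandomize=True, max_examples=100,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture
def constant_weather():
    """Factory for gap-free constant-temperature weather series."""

    def make(tmax: float, tmin: float, ndays: int = 10,
             start: dt.date = dt.date(2022, 1, 1)):
        return [DailyWeather(start + dt.timedelta(days=i), tmax, tmin)
                for i in range(ndays)]

    return make
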