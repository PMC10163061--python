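import datetime

import numpy as np
import pytest
from hypothesis import settings

import cotgrow as cg

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def _day(date, t_max, t_min, e_s=2.0, e_a=1.0, u2=2.0, r_n=13.0, g=0.0):
    return cg.WeatherDay(
        date=date, t_max=t_max, t_min=t_min, e_s=e_s, e_a=e_a, u2=u2, r_n=r_n, g_flux=g
    )


@pytest.fixture
def make_day():
    return _day


@pytest.fixture
def toy_weather():
    """Five mixed days: mid-range, cold-clamped, hot-clamped, ordinary, calm."""
    d0 = datetime.date(2020, 6, 1)
    specs = [
        (30.0, 20.0, 2.5, 1.2, 2.0, 14.0),
        (8.0, 4.0, 1.0, 0.9, 1.0, 6.0),
        (48.0, 40.0, 6.0, 2.0, 3.0, 18.0),
        (25.0, 13.0, 2.2, 1.5, 1.5, 12.0),
        (22.0, 12.0, 2.0, 2.0, 0.0, 10.0),
    ]
    return [
        _day(d0 + datetime.timedelta(days=i), tx, tn, es, ea, u2, rn)
        for i, (tx, tn, es, ea, u2, rn) in enumerate(specs)
    ]


@pytest.fixture(scope="session")
def region_set():
    """Two contrasting simulated region-seasons, shared across tests."""
    return cg.generate_region_set(
        [cg.ARID_CONTINENTAL, cg.WARM_TEMPERATE_MONSOON], year=2020, seed=1
    )


@pytest.fixture(scope="session")
def arid_season(region_set):
    return region_set["arid-continental"]
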