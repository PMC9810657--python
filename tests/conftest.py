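import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from coastalghg import get_gas

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def co2():
    return get_gas("CO2")


@pytest.fixture(scope="session")
def ch4():
    return get_gas("CH4")


def build_stream(
    n_cycles=3,
    start="2020-07-06 00:00:00",
    water_min=35,
    air_min=10,
    period_s=10,
    habitat="macroalgae",
    x_water=(420.0, 30.0),
    x_air=(418.0, 1.95),
    truncate_last_water_min=None,
):
    """Constant-valued analyzer stream with exact cycle structure."""
    rows = []
    t = pd.Timestamp(start)
    period = pd.Timedelta(seconds=period_s)
    for c in range(n_cycles):
        w_min = water_min
        last = c == n_cycles - 1
        if last and truncate_last_water_min is not None:
            w_min = truncate_last_water_min
        for _ in range(int(w_min * 60 / period_s)):
            rows.append((t, "water", habitat, x_water[0], x_water[1], "ok"))
            t += period
        if last and truncate_last_water_min is not None:
            break
        for _ in range(int(air_min * 60 / period_s)):
            rows.append((t, "air", habitat, x_air[0], x_air[1], "ok"))
            t += period
    return pd.DataFrame(
        rows,
        columns=["timestamp", "phase", "habitat", "xco2_ppm", "xch4_ppm", "qc_flag"],
    )


def build_env(start="2020-07-06 00:00:00", hours=3, twater_c=17.0, salinity=6.8,
              wind_ms=4.0, ustar_ms=0.15, zu_m=1.5, pressure_atm=1.0):
    idx = pd.date_range(start, periods=int(hours * 60), freq="1min")
    return pd.DataFrame(
        {
            "timestamp": idx,
            "twater_c": twater_c,
            "salinity": salinity,
            "wind_ms": wind_ms,
            "ustar_ms": ustar_ms,
            "zu_m": zu_m,
            "pressure_atm": pressure_atm,
        }
    )


@pytest.fixture
def stream_factory():
    return build_stream


@pytest.fixture
def env_factory():
    return build_env


@pytest.fixture(scope="session")
def archipelago_groups():
    """Printed surface-water CH4 summaries: macroalgae stand vs two
    open-water control sites (nmol L^-1)."""
    from coastalghg.field_stats import GroupSummary

    return [
        GroupSummary("macroalgae", 56.69, 0.76, 70),
        GroupSummary("open_water_1", 50.41, 1.48, 105),
        GroupSummary("open_water_2", 49.73, 2.48, 119),
    ]
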