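import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def tiny_config():
    """A 10 m x 10 m survey plot with two transects, for ping-level tests."""
    from echosurvey.simulate import SimConfig

    return SimConfig(
        seed=0,
        basin_area_km2=0.0001,
        mean_depth_m=10.0,
        transect_spacing_m=5.0,
        transect_offset_m=1.0,
        class_initial_counts={8: 40},
        per_class_loss_rate_per_day={8: -0.05},
    )


def make_ping(ts, angles_minor=None, angles_major=None, sample_interval=0.018, excluded=None):
    """Hand-built PingRecord from a TS sample array."""
    from echosurvey.simulate import PingRecord

    ts = np.asarray(ts, dtype=float)
    n = len(ts)
    z = np.zeros(n)
    p = PingRecord(
        survey_id="test",
        transect_id=0,
        ping_index=0,
        time=pd.Timestamp("2011-07-26T14:00:00"),
        lat=50.4,
        lon=-96.05,
        range_grid_m=np.arange(n) * sample_interval,
        ts_uncomp_db=ts,
        angle_minor_deg=z if angles_minor is None else np.asarray(angles_minor, float),
        angle_major_deg=z if angles_major is None else np.asarray(angles_major, float),
    )
    p.excluded = excluded
    return p


def clean_echo_ping(
    base_ts=-40.0,
    r_fish=10.0,
    theta_minor=0.0,
    theta_major=0.0,
    noise_floor=-120.0,
    n=1000,
    sample_interval=0.018,
    pulse_length_m=0.298,
    extra_fish=(),
):
    """Ping with one or more quadratic-envelope echoes over a flat floor."""
    from echosurvey.beam import two_way_gain_db

    grid = np.arange(n) * sample_interval
    ts_lin = 10.0 ** (np.full(n, noise_floor) / 10.0)
    ang_mi = np.zeros(n)
    ang_ma = np.zeros(n)
    for bts, rf, tmi, tma in ((base_ts, r_fish, theta_minor, theta_major),) + tuple(extra_fish):
        lvl0 = bts + two_way_gain_db(tmi, tma)
        dr = grid - rf
        inpulse = np.abs(dr) <= pulse_length_m
        lvl = lvl0 - 6.0 * (dr[inpulse] / (pulse_length_m / 2.0)) ** 2
        dominant = 10.0 ** (lvl / 10.0) > ts_lin[inpulse]
        idx = np.nonzero(inpulse)[0][dominant]
        ang_mi[idx] = tmi
        ang_ma[idx] = tma
        ts_lin[inpulse] += 10.0 ** (lvl / 10.0)
    return make_ping(10.0 * np.log10(ts_lin), ang_mi, ang_ma, sample_interval)
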