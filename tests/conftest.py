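import datetime

import numpy as np
import pandas as pd
import pytest

from tas.types import Sensor, SensorSeries, Trajectory, TrajectoryKind


def make_traj(values, kind=TrajectoryKind.JERK, timestamps=None, t0=0, step_ms=1000):
    values = np.asarray(values, dtype=float)
    if timestamps is None:
        timestamps = t0 + np.arange(len(values)) * step_ms
    return Trajectory(np.asarray(timestamps, np.int64), values, kind)


def make_series(sensor, rows, tz_offset_min=0):
    sensor = Sensor(sensor)
    if sensor is Sensor.GPS:
        cols = ["timestamp", "latitude", "longitude", "altitude"]
    elif sensor is Sensor.ACCELEROMETER:
        cols = ["timestamp", "x", "y", "z"]
    else:
        cols = ["timestamp", "state"]
    df = pd.DataFrame(rows, columns=cols)
    return SensorSeries(participant_id="p1", sensor=sensor, events=df,
                        tz_offset_min=tz_offset_min)


@pytest.fixture
def day0():
    return datetime.date(2021, 3, 1)


@pytest.fixture(scope="session")
def routine_gps_traj():
    """Downsampled 28-day synthetic GPS routine shared across tests."""
    from tas.preprocess import downsample_gps
    from tas.simulate import RoutineSpec, generate_sensor_stream

    spec = RoutineSpec(seed=11)
    series = generate_sensor_stream(spec, "gps", 28)
    return downsample_gps(series, interval=120.0)
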