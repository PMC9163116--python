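"""Sensor-specific transforms producing analysis-ready trajectories.

GPS streams are reduced to one modal latitude/longitude pair per fixed
interval (default 30 s) after rounding to a configurable number of decimal
places (default 3, which quantises positions to roughly 110 m cells in
latitude). Accelerometer streams become jerk — the per-second rate of change
of the acceleration magnitude — and screen streams become off-bout durations
preceding each screen-on event. None of the transforms interpolate: gaps in
the data stay gaps.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .types import MS_PER_SECOND, Sensor, SensorSeries, Trajectory, TrajectoryKind

logger = logging.getLogger(__name__)


def _require_sensor(series: SensorSeries, sensor: Sensor, op: str) -> None:
    if series.sensor is not sensor:
        raise TypeError(f"{op} requires a {sensor.value} series, got {series.sensor.value}")


def downsample_gps(
    series: SensorSeries, interval: float = 30.0, decimals: int = 3
) -> Trajectory:
    """Modal (lat, lon) pair per half-open ``interval``-second bin.

    Bins are anchored at the first event's timestamp floored to the interval
    grid (UTC). Within each non-empty bin every pair is rounded to
    ``decimals`` places (round-half-to-even) and the most frequent rounded
    pair is emitted with the bin-start timestamp; ties go to the
    first-observed pair. Empty bins emit nothing.
    """
    _require_sensor(series, Sensor.GPS, "downsample_gps")
    if interval <= 0:
        raise ValueError("interval must be positive")
    if decimals < 0:
        raise ValueError("decimals must be non-negative")
    if len(series) == 0:
        return Trajectory(np.empty(0, np.int64), np.empty((0, 2)), TrajectoryKind.GPS_LATLON)

    ts = series.events["timestamp"].to_numpy()
    interval_ms = int(round(interval * MS_PER_SECOND))
    anchor = (ts[0] // interval_ms) * interval_ms

    df = pd.DataFrame(
        {
            "bin": (ts - anchor) // interval_ms,
            "lat": np.round(series.events["latitude"].to_numpy(), decimals),
            "lon": np.round(series.events["longitude"].to_numpy(), decimals),
        }
    )
    df["order"] = np.arange(len(df))
    counts = (
        df.groupby(["bin", "lat", "lon"], sort=False)
        .agg(n=("order", "size"), first=("order", "min"))
        .reset_index()
    )
    # modal pair per bin; ties broken by earliest first occurrence
    counts = counts.sort_values(["bin", "n", "first"], ascending=[True, False, True])
    winners = counts.drop_duplicates("bin", keep="first").sort_values("bin")

    timestamps = anchor + winners["bin"].to_numpy(np.int64) * interval_ms
    values = winners[["lat", "lon"]].to_numpy(float)
    return Trajectory(timestamps, values, TrajectoryKind.GPS_LATLON)


def compute_jerk(
    series: SensorSeries,
    max_gap: float = 5.0,
    per_second: bool = True,
) -> Trajectory:
    """Rate of change of acceleration magnitude, one value per point after
    the first.

    jerk_i = (|a_i| - |a_{i-1}|) / dt_i with |a| the Euclidean norm of
    (x, y, z) in g-units and dt_i the inter-sample gap in seconds. Pairs
    spanning a gap larger than ``max_gap`` seconds are dropped rather than
    yielding a spuriously tiny rate across missing data. ``per_second=False``
    emits the raw per-sample magnitude difference instead of a rate.
    """
    _require_sensor(series, Sensor.ACCELEROMETER, "compute_jerk")
    empty = Trajectory(np.empty(0, np.int64), np.empty(0), TrajectoryKind.JERK)
    if len(series) < 2:
        logger.warning("compute_jerk: fewer than 2 events, returning empty trajectory")
        return empty

    ev = series.events.drop_duplicates("timestamp", keep="first")
    ts = ev["timestamp"].to_numpy()
    mags = np.linalg.norm(ev[["x", "y", "z"]].to_numpy(float), axis=1)
    if len(ts) < 2:
        return empty

    dt = np.diff(ts) / MS_PER_SECOND
    dmag = np.diff(mags)
    jerk = dmag / dt if per_second else dmag
    keep = dt <= max_gap
    return Trajectory(ts[1:][keep], jerk[keep], TrajectoryKind.JERK)


def compute_screen_bouts(series: SensorSeries) -> Trajectory:
    """Seconds the screen was off before each screen-on event.

    Consecutive duplicate states are collapsed to their first occurrence, so
    repeated "off" reports count from the first off. A screen-on with no
    preceding off (stream start) contributes nothing.
    """
    _require_sensor(series, Sensor.SCREEN, "compute_screen_bouts")
    empty = Trajectory(np.empty(0, np.int64), np.empty(0), TrajectoryKind.SCREEN_OFF_BOUT)
    if len(series) == 0:
        return empty

    states = series.events["state"].to_numpy()
    ts = series.events["timestamp"].to_numpy()
    keep = np.ones(len(states), bool)
    keep[1:] = states[1:] != states[:-1]
    states, ts = states[keep], ts[keep]

    on_idx = np.flatnonzero(states == "on")
    on_idx = on_idx[on_idx > 0]  # needs a predecessor, which is "off" after collapsing
    if on_idx.size == 0:
        return empty
    bouts = (ts[on_idx] - ts[on_idx - 1]) / MS_PER_SECOND
    positive = bouts > 0
    return Trajectory(ts[on_idx][positive], bouts[positive], TrajectoryKind.SCREEN_OFF_BOUT)


def preprocess(series: SensorSeries, **kwargs) -> Trajectory:
    """Dispatch to the sensor-appropriate transform."""
    if series.sensor is Sensor.GPS:
        return downsample_gps(series, **kwargs)
    if series.sensor is Sensor.ACCELEROMETER:
        return compute_jerk(series, **kwargs)
    return compute_screen_bouts(series)
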