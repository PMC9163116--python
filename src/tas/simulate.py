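"""Seeded synthetic smartphone sensor streams with controllable routines.

The generator emulates duty-cycled passive data collection from a phone:
GPS fixes (capped at 1 Hz; emitted every 30 s by default, matching the
resolution the analysis works at), accelerometer triplets at up to 5 Hz,
and irregular screen on/off events. A participant's day is a schedule of
anchor locations (home, work, ...) with commutes linearly traversed between
them, hour-of-day activity and screen-use profiles, white GPS noise well
below the rounding cell, and per-hour dropout. Anomalies — a displaced
location, a schedule shift, or an activity drop — are planted on chosen
dates and hours, optionally coupled to daily survey scores, giving every
pipeline stage a ground truth to recover.

One global seed feeds a splittable per-sensor RNG (numpy SeedSequence
spawn), so each sensor's stream is independently reproducible.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .types import MS_PER_DAY, MS_PER_HOUR, Sensor, SensorSeries

_STREAM_KEYS = {"gps": 0, "accelerometer": 1, "screen": 2, "survey": 3}

#: default anchor schedule: home overnight/evening, work 09-17 local
DEFAULT_ANCHORS = (
    ("home", 42.360, -71.059, ((0.0, 9.0), (17.0, 24.0))),
    ("work", 42.390, -71.120, ((9.0, 17.0),)),
)


@dataclass
class RoutineSpec:
    """Parameters of one participant's simulated daily routine."""

    anchors: tuple = DEFAULT_ANCHORS
    commute_minutes: float = 20.0
    #: hour-of-day jerk intensity (g/s scale of accelerometer fluctuation)
    activity_profile: tuple = tuple(
        0.02 if h < 7 or h >= 23 else 0.3 for h in range(24)
    )
    #: hour-of-day screen-unlock rate (sessions per hour)
    screen_profile: tuple = tuple(
        0.2 if h < 7 or h >= 23 else 4.0 for h in range(24)
    )
    gps_noise_sd: float = 0.0003  # degrees, sub-rounding-cell
    #: per-hour dropout probability; calibrated so that on anomaly-free
    #: streams the default Tukey fence flags <=10% of daily scores
    missingness: float = 0.02
    gps_period_s: float = 30.0    # <= 1 Hz cap
    accel_period_s: float = 0.2   # 5 Hz cap
    start_date: datetime.date = datetime.date(2021, 3, 1)
    tz_offset_min: int = 0
    participant_id: str = "synthetic-001"
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.missingness <= 1.0:
            raise ValueError("missingness must be a probability in [0, 1]")
        if self.gps_period_s < 1.0:
            raise ValueError("gps_period_s below the 1 Hz sampling cap")
        if self.accel_period_s < 0.2:
            raise ValueError("accel_period_s below the 5 Hz sampling cap")
        if len(self.activity_profile) != 24 or len(self.screen_profile) != 24:
            raise ValueError("activity_profile/screen_profile must have 24 entries")
        for name, lat, lon, sched in self.anchors:
            for lo, hi in sched:
                if not (0.0 <= lo < hi <= 24.0):
                    raise ValueError(f"anchor {name!r}: schedule outside 0-24 h")


@dataclass
class AnomalySpec:
    """A planted deviation from routine on chosen dates and hours."""

    dates: tuple = ()
    hours: tuple = tuple(range(24))
    kind: str = "displaced_location"
    magnitude: float = 0.05  # degrees for displacement, hours for shift, [0,1] for drop
    survey_coupling: float = 0.0

    def validate(self) -> None:
        if self.kind not in ("displaced_location", "schedule_shift", "activity_drop"):
            raise ValueError(f"unknown anomaly kind {self.kind!r}")
        if any(h not in range(24) for h in self.hours):
            raise ValueError("hours must be slots 0-23")
        if self.magnitude < 0:
            raise ValueError("magnitude must be non-negative")

    def magnitude_on(self, date: datetime.date) -> float:
        return self.magnitude if date in set(self.dates) else 0.0


def _rng_for(spec: RoutineSpec, stream: str) -> np.random.Generator:
    children = np.random.SeedSequence(spec.seed).spawn(len(_STREAM_KEYS))
    return np.random.default_rng(children[_STREAM_KEYS[stream]])


def _epoch_ms(date: datetime.date) -> int:
    return (date - datetime.date(1970, 1, 1)).days * MS_PER_DAY


def _position_at(spec: RoutineSpec, hour: float) -> tuple[float, float]:
    """Scheduled (lat, lon) at a local fractional hour, commuting linearly."""
    current, starts = None, []
    for name, lat, lon, sched in spec.anchors:
        for lo, hi in sched:
            starts.append((lo, lat, lon))
            if lo <= hour < hi:
                current = (lat, lon, lo)
    if current is None:  # unscheduled hour: stay at first anchor
        return spec.anchors[0][1], spec.anchors[0][2]
    lat, lon, lo = current
    commute_h = spec.commute_minutes / 60.0
    into = hour - lo
    if into < commute_h and lo > 0:
        # linear transition from the previous scheduled position
        prev = _position_at(spec, lo - 1e-9)
        f = into / commute_h
        return prev[0] + f * (lat - prev[0]), prev[1] + f * (lon - prev[1])
    return lat, lon


def generate_sensor_stream(
    spec: RoutineSpec, sensor: Sensor | str, n_days: int
) -> SensorSeries:
    """Generate one sensor's event stream over ``n_days`` days."""
    spec.validate()
    if n_days < 1:
        raise ValueError("n_days must be at least 1")
    sensor = Sensor(sensor)
    rng = _rng_for(spec, sensor.value)
    t0 = _epoch_ms(spec.start_date) - spec.tz_offset_min * 60_000

    if sensor is Sensor.GPS:
        df = _generate_gps(spec, n_days, rng, t0)
    elif sensor is Sensor.ACCELEROMETER:
        df = _generate_accel(spec, n_days, rng, t0)
    else:
        df = _generate_screen(spec, n_days, rng, t0)

    return SensorSeries(
        participant_id=spec.participant_id,
        sensor=sensor,
        events=df,
        tz_offset_min=spec.tz_offset_min,
    )


def _hour_kept(spec: RoutineSpec, n_days: int, rng: np.random.Generator) -> np.ndarray:
    return rng.random((n_days, 24)) >= spec.missingness


def _generate_gps(spec, n_days, rng, t0) -> pd.DataFrame:
    period_ms = int(round(spec.gps_period_s * 1000))
    offsets = np.arange(0, n_days * MS_PER_DAY, period_ms)
    local_hour_f = (offsets % MS_PER_DAY) / MS_PER_HOUR
    day_idx = offsets // MS_PER_DAY
    hour_idx = (offsets % MS_PER_DAY) // MS_PER_HOUR

    kept = _hour_kept(spec, n_days, rng)[day_idx, hour_idx]
    # scheduled positions on a minute grid, then indexed per sample
    grid_hours = np.arange(0, 24 * 60) / 60.0
    grid = np.array([_position_at(spec, h) for h in grid_hours])
    minute = np.minimum((local_hour_f * 60).astype(int), len(grid) - 1)
    pos = grid[minute]

    noise = rng.normal(0.0, spec.gps_noise_sd, size=(len(offsets), 2))
    alt = 10.0 + rng.normal(0.0, 1.0, size=len(offsets))
    df = pd.DataFrame(
        {
            "timestamp": t0 + offsets,
            "latitude": pos[:, 0] + noise[:, 0],
            "longitude": pos[:, 1] + noise[:, 1],
            "altitude": alt,
        }
    )
    return df[kept].reset_index(drop=True)


def _generate_accel(spec, n_days, rng, t0) -> pd.DataFrame:
    period_ms = int(round(spec.accel_period_s * 1000))
    offsets = np.arange(0, n_days * MS_PER_DAY, period_ms)
    day_idx = offsets // MS_PER_DAY
    hour_idx = (offsets % MS_PER_DAY) // MS_PER_HOUR

    kept = _hour_kept(spec, n_days, rng)[day_idx, hour_idx]
    intensity = np.asarray(spec.activity_profile)[hour_idx]
    # gravity on z plus activity-scaled fluctuation on all axes
    xyz = rng.normal(0.0, 1.0, size=(len(offsets), 3)) * intensity[:, None]
    xyz[:, 2] += 1.0
    df = pd.DataFrame(
        {
            "timestamp": t0 + offsets,
            "x": xyz[:, 0],
            "y": xyz[:, 1],
            "z": xyz[:, 2],
        }
    )
    return df[kept].reset_index(drop=True)


def _generate_screen(spec, n_days, rng, t0) -> pd.DataFrame:
    rows = []
    prev_end = -1.0
    for day in range(n_days):
        for hour in range(24):
            rate = spec.screen_profile[hour]
            n_sessions = rng.poisson(rate)
            starts = np.sort(rng.random(n_sessions)) * 3600 + day * 86400 + hour * 3600
            for start in starts:
                if start <= prev_end:  # keep sessions non-overlapping (alternation)
                    continue
                duration = float(rng.exponential(120.0)) + 1.0
                rows.append((start, "on"))
                rows.append((start + duration, "off"))
                prev_end = start + duration
    if not rows:
        return pd.DataFrame(columns=["timestamp", "state"])
    df = pd.DataFrame(rows, columns=["sec", "state"])
    df["timestamp"] = t0 + (df["sec"] * 1000).round().astype(np.int64)
    df = df.sort_values("timestamp", kind="stable").reset_index(drop=True)
    return df[["timestamp", "state"]]


def plant_anomaly(series: SensorSeries, spec: AnomalySpec) -> SensorSeries:
    """Return a copy of the stream with the anomaly applied.

    ``displaced_location`` shifts affected-slot GPS latitude by ``magnitude``
    degrees (a distant pseudo-anchor); ``schedule_shift`` translates affected
    events later by ``magnitude`` hours within their day; ``activity_drop``
    scales accelerometer fluctuation around gravity by (1 - magnitude).
    Events outside the affected dates/hours are untouched.
    """
    spec.validate()
    df = series.events.copy()
    if len(df) == 0:
        return replace(series, events=df)

    local = df["timestamp"].to_numpy() + series.tz_offset_min * 60_000
    epoch_days = local // MS_PER_DAY
    hours = (local % MS_PER_DAY) // MS_PER_HOUR
    target_days = {(d - datetime.date(1970, 1, 1)).days for d in spec.dates}
    mask = np.isin(epoch_days, list(target_days)) & np.isin(hours, list(spec.hours))
    if not mask.any():
        import logging

        logging.getLogger(__name__).warning("anomaly spec does not overlap the stream")
        return replace(series, events=df)

    if spec.kind == "displaced_location":
        if series.sensor is Sensor.GPS:
            df.loc[mask, "latitude"] = df.loc[mask, "latitude"] + spec.magnitude
    elif spec.kind == "schedule_shift":
        shift = int(round(spec.magnitude * MS_PER_HOUR))
        day_end = (epoch_days[mask] + 1) * MS_PER_DAY - 1 - series.tz_offset_min * 60_000
        shifted = np.minimum(df.loc[mask, "timestamp"].to_numpy() + shift, day_end)
        df.loc[mask, "timestamp"] = shifted
        df = df.sort_values("timestamp", kind="stable").reset_index(drop=True)
    elif spec.kind == "activity_drop":
        if series.sensor is Sensor.ACCELEROMETER:
            scale = max(0.0, 1.0 - spec.magnitude)
            for col, g in (("x", 0.0), ("y", 0.0), ("z", 1.0)):
                df.loc[mask, col] = g + (df.loc[mask, col] - g) * scale
    return replace(series, events=df)


def generate_surveys(
    spec: RoutineSpec,
    anomaly: AnomalySpec | None,
    n_days: int,
    effect: float = 0.0,
    noise_sd: float = 0.3,
    instruments: tuple = ("daily_mood", "daily_anxiety"),
    baseline: float = 1.0,
    score_range: tuple = (0.0, 3.0),
) -> pd.DataFrame:
    """Daily self-report scores on a 0-3 Likert scale, optionally coupled to
    the planted anomaly: score = baseline + effect * (that day's anomaly
    magnitude + survey_coupling indicator) + Gaussian noise, clipped to range.
    """
    if effect < 0 or noise_sd < 0:
        raise ValueError("effect and noise_sd must be non-negative")
    rng = _rng_for(spec, "survey")
    rows = []
    for day in range(n_days):
        date = spec.start_date + datetime.timedelta(days=day)
        mag = anomaly.magnitude_on(date) if anomaly is not None else 0.0
        coupling = anomaly.survey_coupling if (anomaly and mag > 0) else 0.0
        for inst in instruments:
            raw = baseline + effect * mag + coupling + rng.normal(0.0, noise_sd)
            rows.append(
                {
                    "participant_id": spec.participant_id,
                    "date": date,
                    "instrument": inst,
                    "score": float(np.clip(raw, *score_range)),
                }
            )
    return pd.DataFrame(rows, columns=["participant_id", "date", "instrument", "score"])


def write_scenario(
    spec: RoutineSpec,
    out_dir: str | Path,
    n_days: int,
    anomaly: AnomalySpec | None = None,
    survey_effect: float = 0.0,
    sensors: tuple = ("gps", "accelerometer", "screen"),
) -> dict:
    """Write sensor CSVs, a survey table and a ground-truth manifest."""
    from .io import write_sensor_stream

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for sensor in sensors:
        series = generate_sensor_stream(spec, sensor, n_days)
        if anomaly is not None:
            series = plant_anomaly(series, anomaly)
        path = out / f"{sensor}.csv"
        write_sensor_stream(series, path)
        paths[sensor] = str(path)

    surveys = generate_surveys(spec, anomaly, n_days, effect=survey_effect)
    surveys.to_csv(out / "surveys.csv", index=False)

    manifest = {
        "participant_id": spec.participant_id,
        "seed": spec.seed,
        "n_days": n_days,
        "start_date": spec.start_date.isoformat(),
        "anomalous_dates": [d.isoformat() for d in (anomaly.dates if anomaly else ())],
        "anomaly_kind": anomaly.kind if anomaly else None,
        "anomaly_hours": list(anomaly.hours) if anomaly else [],
        "sensors": paths,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
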