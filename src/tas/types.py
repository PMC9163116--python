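"""Core containers shared across the pipeline.

A :class:`SensorSeries` is the raw, per-participant event stream for one
sensor; a :class:`Trajectory` is the preprocessed numeric sequence (1-D jerk
or screen-bout values, or 2-D latitude/longitude pairs) that the similarity
metrics compare. Timestamps are UTC epoch milliseconds throughout; local-time
partitioning applies a fixed timezone offset downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

MS_PER_SECOND = 1_000
MS_PER_HOUR = 3_600_000
MS_PER_DAY = 86_400_000


class Sensor(str, Enum):
    GPS = "gps"
    ACCELEROMETER = "accelerometer"
    SCREEN = "screen"


class TrajectoryKind(str, Enum):
    GPS_LATLON = "gps_latlon"
    JERK = "jerk"
    SCREEN_OFF_BOUT = "screen_off_bout"


#: payload column names per sensor, in file order
SENSOR_COLUMNS = {
    Sensor.GPS: ("latitude", "longitude", "altitude"),
    Sensor.ACCELEROMETER: ("x", "y", "z"),
    Sensor.SCREEN: ("state",),
}


@dataclass
class SensorSeries:
    """Raw timestamped event stream for one sensor of one participant.

    ``events`` is a pandas DataFrame with a ``timestamp`` column (int64 epoch
    ms, sorted non-decreasing) plus the sensor's payload columns. Screen
    ``state`` is normalised to lowercase ``on``/``off``.
    """

    participant_id: str
    sensor: Sensor
    events: "pandas.DataFrame"  # noqa: F821 - forward ref avoids import cycle
    tz_offset_min: int = 0
    n_skipped: int = 0
    n_reordered: int = 0

    def __len__(self) -> int:
        return len(self.events)

    def validate(self) -> None:
        ts = self.events["timestamp"].to_numpy()
        if len(ts) and np.any(np.diff(ts) < 0):
            raise ValueError("SensorSeries events must be sorted by timestamp")
        for col in SENSOR_COLUMNS[self.sensor]:
            if col not in self.events.columns:
                raise ValueError(f"missing payload column {col!r}")


@dataclass
class Trajectory:
    """Ordered numeric sequence with strictly increasing timestamps.

    ``values`` has shape (n,) for 1-D kinds (jerk, screen bouts) and (n, 2)
    for GPS latitude/longitude pairs.
    """

    timestamps: np.ndarray
    values: np.ndarray
    kind: TrajectoryKind

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(self.timestamps) != len(self.values):
            raise ValueError("timestamps and values must have equal length")
        if len(self.timestamps) > 1 and np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("Trajectory timestamps must be strictly increasing")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError("Trajectory values must be finite")

    @property
    def ndim_values(self) -> int:
        return 2 if self.values.ndim == 2 else 1

    def __len__(self) -> int:
        return len(self.timestamps)

    def values_2d(self) -> np.ndarray:
        """Values as an (n, d) array (d = 1 or 2) for the metric kernels."""
        v = self.values
        return v.reshape(-1, 1) if v.ndim == 1 else v


@dataclass
class SegmentId:
    """Identity of one compared subseries: local calendar date + slot index."""

    date: "datetime.date"  # noqa: F821
    slot: int

    def __str__(self) -> str:
        return f"{self.date.isoformat()}/{self.slot}"

    def __hash__(self) -> int:
        return hash((self.date, self.slot))


@dataclass
class SegmentGroup:
    """The group G: subseries sharing one temporal characteristic.

    ``segments`` maps each (date, slot) identity to its subtrajectory; all
    members share ``key`` under the temporal rule and span ``resolution_hours``
    hours of local clock time.
    """

    key: str
    resolution_hours: float
    segments: list  # list[tuple[SegmentId, Trajectory]]
    tz_offset_min: int = 0
    n_dropped: int = 0

    @property
    def size(self) -> int:
        return len(self.segments)

    def ids(self) -> list:
        return [sid for sid, _ in self.segments]

    def trajectories(self) -> list:
        return [traj for _, traj in self.segments]


@dataclass
class SimilarityMatrix:
    """l x l symmetric pairwise-distance matrix for one group and one metric.

    ``values`` is a float array with zero diagonal; NaN marks pairs whose
    segments failed the metric's preconditions (excluded downstream, never
    zero-filled).
    """

    group_key: str
    metric: str
    values: np.ndarray
    segment_ids: list
    params: dict = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.segment_ids)

    @property
    def n_missing(self) -> int:
        iu = np.triu_indices(self.size, k=1)
        return int(np.isnan(self.values[iu]).sum())

    def validate(self) -> None:
        v = self.values
        if v.shape != (self.size, self.size):
            raise ValueError("matrix shape does not match segment ids")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("diagonal must be zero")
        mask = ~np.isnan(v)
        if not np.array_equal(mask, mask.T) or not np.allclose(
            v[mask & mask.T], v.T[mask & mask.T]
        ):
            raise ValueError("matrix must be symmetric")
        if np.any(v[mask] < 0):
            raise ValueError("distances must be non-negative")
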