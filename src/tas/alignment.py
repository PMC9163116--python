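"""Temporal alignment: partition trajectories into comparison groups.

A temporal rule R maps each local calendar date to a group key (day-of-week,
weekday vs weekend, or a single all-days group); each day is then sliced into
slots of resolution tau hours of local clock time. The groups' members —
subseries sharing the rule's characteristic — are what the similarity
matrices compare. Local time is UTC plus a fixed minute offset (no DST
shifts), so every slot spans exactly tau hours.
"""

from __future__ import annotations

import datetime
from enum import Enum

import numpy as np

from .types import MS_PER_DAY, MS_PER_HOUR, SegmentGroup, SegmentId, Trajectory

_DAY_NAMES = [
    "Monday", "Tuesday", "Wednesday", "Thursday", "Friday", "Saturday", "Sunday",
]

#: 1970-01-01 was a Thursday; weekday index with Monday = 0
_EPOCH_WEEKDAY = 3


class TemporalRule(str, Enum):
    DAY_OF_WEEK = "day_of_week"
    WEEKDAY_VS_WEEKEND = "weekday_vs_weekend"
    ALL_DAYS = "all_days"

    def key_for_day(self, epoch_day: int) -> str:
        weekday = (epoch_day + _EPOCH_WEEKDAY) % 7
        if self is TemporalRule.DAY_OF_WEEK:
            return _DAY_NAMES[weekday]
        if self is TemporalRule.WEEKDAY_VS_WEEKEND:
            return "weekend" if weekday >= 5 else "weekday"
        return "all"


def _local_ms(traj: Trajectory, tz_offset_min: int) -> np.ndarray:
    return traj.timestamps + int(tz_offset_min) * 60_000


def partition_by_rule(
    traj: Trajectory,
    rule: TemporalRule | str,
    tz_offset_min: int = 0,
    min_points: int = 2,
) -> list[SegmentGroup]:
    """Assign every point to the group of its local calendar date.

    Returns one whole-day (tau = 24) :class:`SegmentGroup` per group key, each
    holding one subtrajectory per local date (slot 0). Daily subseries with
    fewer than ``min_points`` points are dropped and counted on the group.
    """
    rule = TemporalRule(rule)
    if len(traj) == 0:
        return []

    local = _local_ms(traj, tz_offset_min)
    epoch_days = local // MS_PER_DAY

    groups: dict[str, SegmentGroup] = {}
    for day in np.unique(epoch_days):
        key = rule.key_for_day(int(day))
        group = groups.setdefault(
            key, SegmentGroup(key=key, resolution_hours=24.0, segments=[],
                              tz_offset_min=tz_offset_min)
        )
        mask = epoch_days == day
        sub = Trajectory(traj.timestamps[mask], traj.values[mask], traj.kind)
        sid = SegmentId(datetime.date(1970, 1, 1) + datetime.timedelta(days=int(day)), 0)
        if len(sub) < min_points:
            group.n_dropped += 1
        else:
            group.segments.append((sid, sub))
    # stable, rule-defined ordering of keys
    order = {k: i for i, k in enumerate([*_DAY_NAMES, "weekday", "weekend", "all"])}
    return sorted(groups.values(), key=lambda g: order.get(g.key, 99))


def segment_by_resolution(
    group: SegmentGroup, tau: float, min_points: int = 2
) -> SegmentGroup:
    """Split each daily segment into 24/tau slots of local clock time.

    ``tau`` must divide 24. Slot s covers local hours [s*tau, (s+1)*tau);
    slots with fewer than ``min_points`` points are dropped and counted.
    tau = 24 returns the group unchanged.
    """
    if tau <= 0 or tau > 24 or (24.0 / tau) != int(24.0 / tau):
        raise ValueError(f"tau must divide 24 hours, got {tau}")
    if tau == 24:
        return group

    slot_ms = int(tau * MS_PER_HOUR)
    out = SegmentGroup(
        key=group.key,
        resolution_hours=float(tau),
        segments=[],
        tz_offset_min=group.tz_offset_min,
        n_dropped=group.n_dropped,
    )
    for sid, sub in group.segments:
        local = _local_ms(sub, group.tz_offset_min)
        slots = (local % MS_PER_DAY) // slot_ms
        for slot in np.unique(slots):
            mask = slots == slot
            piece = Trajectory(sub.timestamps[mask], sub.values[mask], sub.kind)
            if len(piece) < min_points:
                out.n_dropped += 1
            else:
                out.segments.append((SegmentId(sid.date, int(slot)), piece))
    return out


def align(
    traj: Trajectory,
    rule: TemporalRule | str,
    tau: float = 24.0,
    tz_offset_min: int = 0,
    min_points: int = 2,
) -> list[SegmentGroup]:
    """Partition by rule, then slice by resolution — the full alignment step."""
    groups = partition_by_rule(traj, rule, tz_offset_min, min_points=min_points)
    return [segment_by_resolution(g, tau, min_points=min_points) for g in groups]


def segment_manifest(groups: list[SegmentGroup]) -> "pandas.DataFrame":  # noqa: F821
    """Tabulate kept segments: group_key, date, slot, n_points, kept."""
    import pandas as pd

    rows = [
        {
            "group_key": g.key,
            "date": sid.date.isoformat(),
            "slot": sid.slot,
            "n_points": len(sub),
            "kept": True,
        }
        for g in groups
        for sid, sub in g.segments
    ]
    return pd.DataFrame(rows, columns=["group_key", "date", "slot", "n_points", "kept"])
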