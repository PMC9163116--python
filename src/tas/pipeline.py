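"""End-to-end orchestration: preprocess -> align -> similarity -> score.

A :class:`RunConfig` (YAML file or keyword arguments) names the input
streams and the analysis parameters; :func:`run_pipeline` executes the
stages, writes every intermediate artifact into the run directory and drops
a provenance manifest (the verbatim config plus package version) alongside,
so any stage can be re-run exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .alignment import align, segment_manifest
from .io import read_sensor_stream
from .preprocess import compute_jerk, compute_screen_bouts, downsample_gps
from .scoring import (
    correlate_with_surveys,
    daily_score_table,
    flag_anomalies,
    hourly_score_distribution,
    tas_scores,
)
from .similarity import similarity_matrix
from .types import Sensor

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    sensor_paths: dict = field(default_factory=dict)  # sensor name -> file path
    survey_path: str | None = None
    out_dir: str = "tas_run"
    rule: str = "day_of_week"
    tau: float = 24.0
    metrics: tuple = ("dtw",)
    epsilon: float | None = None
    gps_interval: float = 30.0
    gps_decimals: int = 3
    tz_offset_min: int = 0
    min_points: int = 2
    aggregation: str = "mean"
    flag_method: str = "tukey"
    flag_k: float = 1.5
    pairing: str = "pooled"
    participant_id: str = ""

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "metrics" in data:
            data["metrics"] = tuple(data["metrics"])
        return cls(**data)

    def validate(self) -> None:
        if not self.sensor_paths:
            raise ValueError("config must name at least one sensor path")
        for sensor in self.sensor_paths:
            Sensor(sensor)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["metrics"] = list(d["metrics"])
        return d


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""


def _preprocess_one(config: RunConfig, sensor: Sensor, path: str):
    series = read_sensor_stream(
        path, sensor, participant_id=config.participant_id,
        tz_offset_min=config.tz_offset_min,
    )
    if sensor is Sensor.GPS:
        return downsample_gps(series, interval=config.gps_interval,
                              decimals=config.gps_decimals)
    if sensor is Sensor.ACCELEROMETER:
        return compute_jerk(series)
    return compute_screen_bouts(series)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the provenance manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "stages": {},
        "skipped_sensors": [
            s.value for s in Sensor if s.value not in config.sensor_paths
        ],
    }

    all_daily: dict = {}
    for sensor_name, path in config.sensor_paths.items():
        sensor = Sensor(sensor_name)
        try:
            traj = _preprocess_one(config, sensor, path)
        except Exception as exc:
            raise StageError(f"preprocess[{sensor_name}]: {exc}") from exc
        logger.info("preprocess[%s]: %d points", sensor_name, len(traj))
        if len(traj) == 0:
            manifest["stages"][sensor_name] = {"n_points": 0, "note": "empty trajectory"}
            continue

        groups = align(traj, config.rule, tau=config.tau,
                       tz_offset_min=config.tz_offset_min, min_points=config.min_points)
        segment_manifest(groups).to_csv(out / f"{sensor_name}_segments.csv", index=False)
        n_dropped = sum(g.n_dropped for g in groups)
        logger.info("align[%s]: %d group(s), %d segment(s) dropped",
                    sensor_name, len(groups), n_dropped)

        sensor_info = {"n_points": len(traj), "n_groups": len(groups),
                       "n_dropped_segments": n_dropped, "metrics": {}}
        for metric in config.metrics:
            tables = []
            for group in groups:
                if group.size < 2:
                    logger.info("score[%s/%s]: group %s too small, skipped",
                                sensor_name, metric, group.key)
                    continue
                try:
                    params = {} if config.epsilon is None else {"epsilon": config.epsilon}
                    mat = similarity_matrix(group, metric, params)
                except Exception as exc:
                    raise StageError(
                        f"similarity[{sensor_name}/{metric}/{group.key}]: {exc}"
                    ) from exc
                _write_matrix(mat, out / f"{sensor_name}_{metric}_{group.key}.csv")
                tables.append(tas_scores(mat, aggregation=config.aggregation))

            if not tables:
                continue
            scored = flag_anomalies(
                pd.concat(tables, ignore_index=True),
                method=config.flag_method, k=config.flag_k,
            )
            scored.insert(0, "participant_id", config.participant_id)
            scored.to_csv(out / f"{sensor_name}_{metric}_scores.csv", index=False)

            per_group = [g for _, g in scored.groupby("group_key")]
            daily = daily_score_table(per_group)
            daily.to_csv(out / f"{sensor_name}_{metric}_daily.csv")
            all_daily[(sensor_name, metric)] = daily
            if config.tau == 1.0:
                hourly_score_distribution(per_group).to_csv(
                    out / f"{sensor_name}_{metric}_hourly.csv", index=False
                )
            sensor_info["metrics"][metric] = {
                "n_scores": len(scored),
                "n_flagged": int(scored["is_anomaly"].sum()),
            }
        manifest["stages"][sensor_name] = sensor_info

    if config.survey_path and all_daily:
        surveys = pd.read_csv(config.survey_path, parse_dates=["date"])
        surveys["date"] = surveys["date"].dt.date
        reports = []
        for (sensor_name, metric), daily in all_daily.items():
            for inst in sorted(surveys["instrument"].unique()):
                try:
                    rep = correlate_with_surveys(daily, surveys, instrument=inst,
                                                 pairing=config.pairing)
                except ValueError as exc:
                    logger.info("correlate[%s/%s/%s]: %s", sensor_name, metric, inst, exc)
                    continue
                reports.append({"sensor": sensor_name, "survey": inst,
                                "metric": metric, **rep})
        (out / "correlations.json").write_text(json.dumps(reports, indent=2))
        manifest["stages"]["correlations"] = {"n_reports": len(reports)}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _write_matrix(mat, path: Path) -> None:
    labels = [str(s) for s in mat.segment_ids]
    pd.DataFrame(mat.values, index=labels, columns=labels).to_csv(path)
    sidecar = {
        "group_key": mat.group_key,
        "metric": mat.metric,
        "params": mat.params,
        "n_missing": mat.n_missing,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
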