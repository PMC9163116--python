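"""Reading raw sensor streams from CSV or JSON-lines files.

Expected schemas (header names are fixed): GPS ``timestamp,latitude,
longitude,altitude``; accelerometer ``timestamp,x,y,z``; screen
``timestamp,state`` with state in {on, off} (case-insensitive). Timestamps
are integer epoch milliseconds or ISO-8601 strings.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .types import SENSOR_COLUMNS, Sensor, SensorSeries

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    """A required column is missing from the input file."""


def _parse_timestamps(col: pd.Series) -> pd.Series:
    """Epoch-ms integers pass through; anything else is parsed as ISO-8601."""
    numeric = pd.to_numeric(col, errors="coerce")
    if numeric.notna().all():
        return numeric.astype("int64")
    parsed = pd.to_datetime(col, errors="coerce", utc=True, format="ISO8601")
    out = (parsed.astype("int64") // 10**6).where(parsed.notna(), other=pd.NA)
    # mixed files: fall back to numeric where ISO parsing failed
    out = out.where(numeric.isna(), other=numeric)
    return out


def read_sensor_stream(
    path: str | Path,
    sensor: Sensor | str,
    *,
    participant_id: str = "",
    tz_offset_min: int = 0,
) -> SensorSeries:
    """Read one sensor's event stream into a :class:`SensorSeries`.

    The file format is inferred from the extension (``.jsonl``/``.json`` =
    JSON lines, otherwise CSV). Rows with unparseable fields are counted and
    skipped; exact duplicate rows are dropped; out-of-order rows are sorted
    with the number of displaced rows logged.
    """
    sensor = Sensor(sensor)
    path = Path(path)
    cols = ("timestamp", *SENSOR_COLUMNS[sensor])

    suffix = path.suffix.lower()
    if suffix in {".jsonl", ".json", ".ndjson"}:
        try:
            df = pd.read_json(path, lines=True, dtype=False)
        except ValueError:
            df = pd.DataFrame(columns=cols)
    else:
        df = pd.read_csv(path, dtype=str)
    if df.empty and not df.columns.tolist():
        df = pd.DataFrame(columns=cols)

    for col in cols:
        if col not in df.columns:
            raise SchemaError(f"{path.name}: missing required column {col!r}")
    df = df.loc[:, list(cols)].copy()

    n_in = len(df)
    df["timestamp"] = _parse_timestamps(df["timestamp"])
    if sensor is Sensor.SCREEN:
        state = df["state"].astype(str).str.strip().str.lower()
        df["state"] = state.where(state.isin(["on", "off"]), other=pd.NA)
    else:
        for col in SENSOR_COLUMNS[sensor]:
            df[col] = pd.to_numeric(df[col], errors="coerce")
        numeric_cols = list(SENSOR_COLUMNS[sensor])
        df[numeric_cols] = df[numeric_cols].where(
            np.isfinite(df[numeric_cols].astype(float)), other=pd.NA
        )

    df = df.dropna()
    n_skipped = n_in - len(df)
    if n_skipped:
        logger.info("%s: skipped %d unparseable row(s)", path.name, n_skipped)

    df = df.drop_duplicates()
    df["timestamp"] = df["timestamp"].astype("int64")
    if sensor is not Sensor.SCREEN:
        for col in SENSOR_COLUMNS[sensor]:
            df[col] = df[col].astype(float)

    order = df["timestamp"].to_numpy().argsort(kind="stable")
    n_reordered = int((order != np.arange(len(order))).sum())
    if n_reordered:
        logger.info("%s: sorted input, %d row(s) displaced", path.name, n_reordered)
        df = df.iloc[order]
    df = df.reset_index(drop=True)

    series = SensorSeries(
        participant_id=participant_id,
        sensor=sensor,
        events=df,
        tz_offset_min=tz_offset_min,
        n_skipped=n_skipped,
        n_reordered=n_reordered,
    )
    series.validate()
    return series


def write_sensor_stream(series: SensorSeries, path: str | Path) -> None:
    """Write a SensorSeries back to CSV or JSONL (inverse of reading)."""
    path = Path(path)
    if path.suffix.lower() in {".jsonl", ".json", ".ndjson"}:
        series.events.to_json(path, orient="records", lines=True)
    else:
        series.events.to_csv(path, index=False)
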