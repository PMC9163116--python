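"""TAS scores, anomaly flags, calendar/clock tables and survey correlation.

A segment's TAS score is the aggregate (mean by default, median for
robustness) of its off-diagonal row in the group's similarity matrix: high
score = the segment deviates from the rest of its group. Flags come from a
Tukey fence (score > Q3 + k*IQR, k = 1.5) or a quantile rule. Daily and
hourly tables back calendar-heatplot and clock-plot views; Pearson
correlation relates daily scores to self-report survey scores.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

SCORE_COLUMNS = ["group_key", "date", "slot", "metric", "score", "is_anomaly"]


def tas_scores(matrix: "SimilarityMatrix", aggregation: str = "mean") -> pd.DataFrame:  # noqa: F821
    """Per-segment dissimilarity scores from one similarity matrix.

    Score of segment i = mean (or median) of row i's off-diagonal, non-missing
    entries. Rows with no usable entries are omitted with a logged reason.
    Returns a DataFrame with columns group_key, date, slot, metric, score,
    is_anomaly (initialised False).
    """
    if aggregation not in ("mean", "median"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    v = matrix.values.copy()
    np.fill_diagonal(v, np.nan)

    rows = []
    agg = np.nanmean if aggregation == "mean" else np.nanmedian
    for i, sid in enumerate(matrix.segment_ids):
        row = v[i]
        if np.all(np.isnan(row)):
            logger.info("segment %s omitted: no comparable partners", sid)
            continue
        rows.append(
            {
                "group_key": matrix.group_key,
                "date": sid.date,
                "slot": sid.slot,
                "metric": matrix.metric,
                "score": float(agg(row)),
                "is_anomaly": False,
            }
        )
    return pd.DataFrame(rows, columns=SCORE_COLUMNS)


def flag_anomalies(
    table: pd.DataFrame, method: str = "tukey", k: float = 1.5, q: float = 0.75
) -> pd.DataFrame:
    """Flag outlying scores within each group_key.

    ``tukey``: flag score > Q3 + k*IQR (default k = 1.5). ``quantile``: flag
    the top (1-q) fraction by rank, which makes the flags invariant under any
    strictly increasing transform of the scores. Groups with fewer than 3
    scores are left unflagged with a log line.
    """
    out = table.copy()
    out["is_anomaly"] = False
    for key, idx in out.groupby("group_key").groups.items():
        scores = out.loc[idx, "score"].to_numpy()
        n = len(scores)
        if n < 3:
            logger.info("group %s: only %d score(s), skipping anomaly flags", key, n)
            continue
        if method == "tukey":
            q1, q3 = np.percentile(scores, [25, 75])
            flags = scores > q3 + k * (q3 - q1)
        elif method == "quantile":
            n_flag = int(np.floor((1.0 - q) * n + 1e-9))
            flags = np.zeros(n, bool)
            if n_flag > 0:
                order = np.argsort(-scores, kind="stable")
                flags[order[:n_flag]] = True
        else:
            raise ValueError(f"unknown method {method!r}")
        out.loc[idx, "is_anomaly"] = flags
    return out


def daily_score_table(tables: list[pd.DataFrame]) -> pd.Series:
    """One score per calendar date: the calendar-heatplot input.

    Whole-day (tau = 24) scores map straight onto dates; finer-resolution
    scores are averaged over each date's retained slots. Dates inside the
    observed span with no retained segment stay NaN — never imputed.
    """
    frames = [t for t in tables if len(t)]
    if not frames:
        return pd.Series(dtype=float, name="score")
    allrows = pd.concat(frames, ignore_index=True)
    daily = allrows.groupby("date")["score"].mean()
    full = pd.date_range(daily.index.min(), daily.index.max(), freq="D").date
    daily = daily.reindex(full)
    daily.index.name = "date"
    daily.name = "score"
    return daily


def hourly_score_distribution(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """24-slot profile of mean scores: the clock-plot input.

    Requires tables computed at hourly resolution. Returns a DataFrame with
    columns slot (0-23), mean_score (NaN where no data), n, and rank
    (1 = most dissimilar period of the day).
    """
    frames = [t for t in tables if len(t)]
    slots = pd.DataFrame({"slot": np.arange(24)})
    if not frames:
        slots["mean_score"] = np.nan
        slots["n"] = 0
        slots["rank"] = np.nan
        return slots
    allrows = pd.concat(frames, ignore_index=True)
    if allrows["slot"].max() > 23:
        raise ValueError("hourly profile needs scores at tau = 1 (slots 0-23)")
    prof = allrows.groupby("slot")["score"].agg(mean_score="mean", n="size").reset_index()
    out = slots.merge(prof, on="slot", how="left")
    out["n"] = out["n"].fillna(0).astype(int)
    out["rank"] = out["mean_score"].rank(ascending=False, method="min")
    return out


def correlate_with_surveys(
    daily_scores: pd.Series,
    surveys: pd.DataFrame,
    instrument: str | None = None,
    pairing: str = "pooled",
) -> dict:
    """Pearson correlation between daily TAS scores and daily survey scores.

    ``surveys`` needs columns date, score and optionally participant_id and
    instrument (filtered when ``instrument`` is given). Pairing ``pooled``
    correlates all matched participant-days at once; ``per_participant``
    averages per-participant coefficients (p from a t-test on the Fisher-z
    transformed coefficients). Survey dates with no score that day are
    dropped. Raises on fewer than 3 matched pairs or zero variance.
    """
    sv = surveys.copy()
    if instrument is not None and "instrument" in sv.columns:
        sv = sv[sv["instrument"] == instrument]
    scores = daily_scores.dropna()
    sv = sv[sv["date"].isin(scores.index)]
    sv = sv.assign(tas=sv["date"].map(scores))

    def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
        if len(x) < 3:
            raise ValueError("correlation undefined: fewer than 3 matched pairs")
        if np.std(x) == 0 or np.std(y) == 0:
            raise ValueError("correlation undefined: zero variance")
        r, p = stats.pearsonr(x, y)
        return float(r), float(p)

    if pairing == "pooled" or "participant_id" not in sv.columns:
        rho, p = _pearson(sv["tas"].to_numpy(float), sv["score"].to_numpy(float))
        n_pairs = len(sv)
    elif pairing == "per_participant":
        rs = []
        n_pairs = 0
        for _, part in sv.groupby("participant_id"):
            r, _ = _pearson(part["tas"].to_numpy(float), part["score"].to_numpy(float))
            rs.append(r)
            n_pairs += len(part)
        rho = float(np.mean(rs))
        if len(rs) >= 2:
            z = np.arctanh(np.clip(rs, -0.999999, 0.999999))
            p = float(stats.ttest_1samp(z, 0.0).pvalue)
        else:
            p = float("nan")
    else:
        raise ValueError(f"unknown pairing {pairing!r}")

    return {"rho": rho, "p": p, "n_pairs": int(n_pairs), "pairing": pairing}
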