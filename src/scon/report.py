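"""Diel summaries of release-event streams.

Two views of the daily rhythm: an hour-of-day table (per day, or averaged
over day ranges of a registration period) and a minute-resolution count
series.  Both conserve event totals; minutes falling inside declared data
gaps are reported as missing rather than zero.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .simulate import DEFAULT_NIGHT_END_H, DEFAULT_NIGHT_START_H

SECONDS_PER_DAY = 86_400


def is_night(hour: np.ndarray | float,
             night_mask: tuple[float, float] = (DEFAULT_NIGHT_START_H,
                                                DEFAULT_NIGHT_END_H)) -> np.ndarray:
    """True for clock hours inside the (midnight-wrapping) night mask."""
    start, end = night_mask
    h = np.asarray(hour, dtype=np.float64)
    return (h >= start) | (h < end) if start > end else (h >= start) & (h < end)


def hourly_summary(
    events: np.ndarray | Sequence[int],
    night_mask: tuple[float, float] = (DEFAULT_NIGHT_START_H, DEFAULT_NIGHT_END_H),
    grouping: str = "per-day",
    periods: Sequence[tuple[int, int]] = ((1, 6), (10, 18)),
) -> pd.DataFrame:
    """Hour-of-day event counts, per day or averaged over period day ranges.

    ``grouping="per-day"`` returns one row per (day, hour) with the count;
    ``"period-average"`` averages the hourly counts over the inclusive day
    ranges in ``periods`` (days numbered from 1 at the first day observed).
    Empty input yields an all-zero single-day table.
    """
    t = np.asarray(events, dtype=np.int64)
    if t.size == 0:
        base = pd.DataFrame({"day": 1, "hour": np.arange(24), "count": 0})
        base["is_night"] = is_night(base["hour"].to_numpy(), night_mask)
        if grouping == "per-day":
            return base
        base = base.rename(columns={"count": "mean_count"})
        return base.assign(period="1-1")[["period", "hour", "mean_count", "is_night"]]
    day0 = int(t.min()) // SECONDS_PER_DAY
    day = t // SECONDS_PER_DAY - day0 + 1  # 1-based study day
    hour = (t % SECONDS_PER_DAY) // 3600
    n_days = int(day.max())
    grid = pd.MultiIndex.from_product([np.arange(1, n_days + 1), np.arange(24)],
                                      names=["day", "hour"])
    counts = (pd.Series(1, index=pd.MultiIndex.from_arrays([day, hour],
                                                           names=["day", "hour"]))
              .groupby(level=["day", "hour"]).sum()
              .reindex(grid, fill_value=0).rename("count").reset_index())
    counts["is_night"] = is_night(counts["hour"].to_numpy(), night_mask)
    if grouping == "per-day":
        return counts
    if grouping != "period-average":
        raise ValueError(f"unknown grouping: {grouping!r}")
    rows = []
    for lo, hi in periods:
        sel = counts[(counts["day"] >= lo) & (counts["day"] <= hi)]
        mean = sel.groupby("hour", as_index=False)["count"].mean()
        mean = mean.rename(columns={"count": "mean_count"})
        mean.insert(0, "period", f"{lo}-{hi}")
        mean["is_night"] = is_night(mean["hour"].to_numpy(), night_mask)
        rows.append(mean)
    return pd.concat(rows, ignore_index=True)


def per_minute_series(
    events: np.ndarray | Sequence[int],
    span: tuple[int, int],
    gaps: Sequence[tuple[int, int]] = (),
) -> pd.Series:
    """Minute-resolution counts over ``span`` (half-open minutes).

    Minutes intersecting a declared gap are NaN (data missing, not zero);
    all other minutes report their event count, so the sum over non-gap
    minutes equals the number of events outside gaps.
    """
    t = np.asarray(events, dtype=np.int64)
    lo = (int(span[0]) // 60) * 60
    hi = int(span[1])
    if t.size and (t.min() < lo or t.max() >= hi):
        raise ValueError("events outside span")
    edges = np.arange(lo, hi + 60, 60, dtype=np.int64)
    counts, _ = np.histogram(t, bins=edges)
    ser = pd.Series(counts.astype(np.float64), index=edges[:-1], name="per_minute")
    for a, b in gaps:
        mask = (ser.index < b) & (ser.index + 60 > a)
        ser[mask] = np.nan
    return ser
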