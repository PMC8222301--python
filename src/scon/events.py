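"""Event-stream I/O, bubble pooling, and analysis-window partitioning.

The raw observational unit is a *bubble record*: one detected gas-bubble
trace with an absolute timestamp at seconds resolution.  Because a single
fish may expel several bursts in quick succession, bubbles arriving within
a short pooling interval (10 s by default) are collapsed into one *release
event* stamped at the first bubble of the burst.  Release events are then
partitioned into non-overlapping clock-aligned windows for the
connectivity analysis; within a window each event is re-expressed as an
integer offset in ``[1, window_length]``.

All internal time arithmetic is in integer epoch seconds (UTC).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SECONDS_PER_DAY = 86_400

#: Window lengths used throughout the analysis (1, 5, 30 min; 1, 2, 4, 6 h).
CANONICAL_WINDOW_LENGTHS = (60, 300, 1800, 3600, 7200, 14400, 21600)


@dataclass(frozen=True)
class PoolingConfig:
    """How bubble records are collapsed into release events.

    ``pool_interval_s = 0`` disables pooling (every bubble is its own
    event).  ``mode`` selects the pooling semantics: ``"anchored"`` opens a
    fixed-length window at the first bubble of a burst, ``"gap"`` chains
    bubbles whenever consecutive gaps stay within the interval.
    """

    pool_interval_s: int = 10
    mode: str = "anchored"

    def __post_init__(self) -> None:
        if self.pool_interval_s < 0:
            raise ValueError("pool_interval_s must be >= 0")
        if self.mode not in ("anchored", "gap"):
            raise ValueError(f"unknown pooling mode: {self.mode!r}")


@dataclass(frozen=True)
class AnalysisWindow:
    """One clock-aligned interval with its events as 1-based offsets.

    ``offsets`` are integer seconds since the window start, clamped to
    ``[1, length_s]`` and sorted non-decreasing.
    """

    start: int
    length_s: int
    offsets: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        off = np.asarray(self.offsets, dtype=np.int64)
        object.__setattr__(self, "offsets", off)
        if off.size and (off.min() < 1 or off.max() > self.length_s):
            raise ValueError("offsets must lie in [1, length_s]")
        if np.any(np.diff(off) < 0):
            raise ValueError("offsets must be sorted non-decreasing")

    @property
    def n_events(self) -> int:
        return int(self.offsets.size)


@dataclass(frozen=True)
class PartitionResult:
    """Outcome of partitioning an event series into analysis windows."""

    windows: list[AnalysisWindow]
    length_s: int
    n_excluded_min_events: int
    n_events_in_excluded: int
    n_windows_masked: int
    n_events_masked: int

    @property
    def n_analyzed(self) -> int:
        return len(self.windows)

    @property
    def n_events_analyzed(self) -> int:
        return sum(w.n_events for w in self.windows)


def parse_times(values: Iterable, *, context: str = "time") -> np.ndarray:
    """Parse ISO-8601 strings or epoch seconds into integer epoch seconds.

    Sub-second precision is floored.  Naive timestamps are taken as UTC.
    Raises ``ValueError`` naming the first offending row (1-based, data
    rows) on unparseable input.
    """
    ser = pd.Series(list(values))
    if ser.empty:
        return np.array([], dtype=np.int64)
    numeric = pd.to_numeric(ser, errors="coerce")
    if numeric.notna().all():
        return np.floor(numeric.to_numpy(dtype=np.float64)).astype(np.int64)
    parsed = pd.to_datetime(ser, errors="coerce", utc=True, format="ISO8601")
    bad = parsed.isna() & ser.notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise ValueError(
            f"unparseable {context} at data row {row}: {ser.iloc[row - 1]!r}"
        )
    if parsed.isna().any():
        row = int(np.flatnonzero(parsed.isna().to_numpy())[0]) + 1
        raise ValueError(f"missing {context} at data row {row}")
    return (parsed.astype("int64").to_numpy() // 1_000_000_000).astype(np.int64)


def read_bubble_csv(path: str | Path, time_column: str = "time") -> np.ndarray:
    """Read a bubble (or event) stream CSV into sorted integer epoch seconds.

    The file must have a header row; ``time_column`` holds ISO-8601
    timestamps (with or without zone; naive means UTC) or epoch seconds.
    An empty file yields an empty array.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        logger.info("read %s: empty file", path)
        return np.array([], dtype=np.int64)
    if df.empty and time_column not in df.columns:
        logger.info("read %s: 0 rows", path)
        return np.array([], dtype=np.int64)
    if time_column not in df.columns:
        raise ValueError(f"{path}: missing column {time_column!r}")
    n_raw = len(df)
    col = df[time_column]
    n_blank = int(col.isna().sum())
    col = col.dropna()
    times = parse_times(col, context=time_column)
    times.sort()
    logger.info("read %s: %d rows read, %d dropped (blank)", path, n_raw, n_blank)
    return times


def pool_bubbles(
    bubbles: np.ndarray | Sequence[int],
    cfg: PoolingConfig | int = PoolingConfig(),
) -> tuple[np.ndarray, np.ndarray]:
    """Collapse sorted bubble times into release events.

    Under the default anchored rule the first unassigned bubble opens an
    event; every later bubble within ``pool_interval_s`` seconds of that
    *anchor* joins it (boundary inclusive), and the first bubble beyond
    opens the next event.  Under the ``gap`` rule a bubble joins the open
    event whenever its gap to the *previous bubble* is within the interval.

    Returns ``(event_times, n_bubbles_pooled)``; each event is stamped at
    the first bubble of its burst.
    """
    if isinstance(cfg, int):
        cfg = PoolingConfig(pool_interval_s=cfg)
    t = np.asarray(bubbles, dtype=np.int64)
    if np.any(np.diff(t) < 0):
        raise ValueError("bubble times must be sorted ascending")
    if t.size == 0:
        return t.copy(), np.array([], dtype=np.int64)
    if cfg.pool_interval_s == 0 and cfg.mode == "anchored":
        # ties still pool: Δt = 0 <= 0
        anchors = np.flatnonzero(np.concatenate(([True], np.diff(t) > 0)))
    elif cfg.mode == "anchored":
        anchors = [0]
        anchor = t[0]
        for i in range(1, t.size):
            if t[i] - anchor > cfg.pool_interval_s:
                anchors.append(i)
                anchor = t[i]
        anchors = np.asarray(anchors)
    else:  # gap-chaining
        gaps = np.diff(t)
        anchors = np.flatnonzero(
            np.concatenate(([True], gaps > cfg.pool_interval_s))
        )
    counts = np.diff(np.concatenate((anchors, [t.size])))
    return t[anchors].copy(), counts.astype(np.int64)


def partition_windows(
    events: np.ndarray | Sequence[int],
    length_s: int,
    span: tuple[int, int],
    min_events: int = 2,
    gaps: Sequence[tuple[int, int]] = (),
) -> PartitionResult:
    """Tile ``span`` with clock-aligned windows and assign event offsets.

    Windows of ``length_s`` seconds are tiled from midnight (UTC) of each
    day touched by ``span``; offsets are ``ceil(t - start)`` clamped to
    ``[1, length_s]``.  Windows holding fewer than ``min_events`` events
    are excluded but counted; windows intersecting a declared data gap
    ``(gap_start, gap_end)`` are dropped entirely.
    """
    if length_s <= 0:
        raise ValueError("length_s must be positive")
    if SECONDS_PER_DAY % length_s != 0 and length_s not in CANONICAL_WINDOW_LENGTHS:
        raise ValueError(
            f"length_s={length_s} must divide 86400 or be one of "
            f"{CANONICAL_WINDOW_LENGTHS}"
        )
    t = np.asarray(events, dtype=np.int64)
    span_start, span_end = int(span[0]), int(span[1])
    if t.size and (t.min() < span_start or t.max() >= span_end):
        offenders = t[(t < span_start) | (t >= span_end)]
        raise ValueError(
            f"{offenders.size} event(s) outside span, e.g. {offenders[:5].tolist()}"
        )

    day0 = (span_start // SECONDS_PER_DAY) * SECONDS_PER_DAY
    n_windows = int(np.ceil((span_end - day0) / length_s))
    gap_arr = [(int(a), int(b)) for a, b in gaps]

    # events -> window index relative to day0 (uniform tiling; length_s
    # divides a day so windows never straddle midnight)
    idx = (t - day0) // length_s if t.size else np.array([], dtype=np.int64)

    windows: list[AnalysisWindow] = []
    n_small = 0
    ev_small = 0
    n_masked = 0
    ev_masked = 0
    # group event positions per window
    order = np.argsort(idx, kind="stable")
    idx_sorted = idx[order]
    t_sorted = t[order]
    boundaries = np.searchsorted(idx_sorted, np.arange(n_windows + 1))
    for k in range(n_windows):
        lo, hi = boundaries[k], boundaries[k + 1]
        w_start = day0 + k * length_s
        w_end = w_start + length_s
        masked = any(a < w_end and b > w_start for a, b in gap_arr)
        if masked:
            n_masked += 1
            ev_masked += hi - lo
            continue
        if hi - lo < min_events:
            if hi - lo > 0:
                n_small += 1
                ev_small += hi - lo
            continue
        off = np.clip(t_sorted[lo:hi] - w_start, 1, length_s)
        windows.append(AnalysisWindow(start=int(w_start), length_s=length_s,
                                      offsets=np.sort(off)))
    return PartitionResult(
        windows=windows,
        length_s=length_s,
        n_excluded_min_events=n_small,
        n_events_in_excluded=ev_small,
        n_windows_masked=n_masked,
        n_events_masked=ev_masked,
    )


def write_events(
    events: np.ndarray | Sequence[int],
    path: str | Path,
    n_bubbles_pooled: np.ndarray | Sequence[int] | None = None,
) -> None:
    """Write release events as CSV (columns ``time``, ``n_bubbles_pooled``).

    Times are written as integer epoch seconds so a write/read round trip
    is exact.
    """
    t = np.asarray(events, dtype=np.int64)
    if np.any(np.diff(t) < 0):
        raise ValueError("events must be sorted")
    nb = (np.ones(t.size, dtype=np.int64) if n_bubbles_pooled is None
          else np.asarray(n_bubbles_pooled, dtype=np.int64))
    pd.DataFrame({"time": t, "n_bubbles_pooled": nb}).to_csv(path, index=False)


def read_events(path: str | Path) -> np.ndarray:
    """Read a release-event CSV written by :func:`write_events`."""
    return read_bubble_csv(path, time_column="time")


def infer_span(events: np.ndarray) -> tuple[int, int]:
    """Smallest whole-day UTC span covering all events."""
    t = np.asarray(events, dtype=np.int64)
    if t.size == 0:
        raise ValueError("cannot infer span from an empty event stream")
    lo = (int(t.min()) // SECONDS_PER_DAY) * SECONDS_PER_DAY
    hi = (int(t.max()) // SECONDS_PER_DAY + 1) * SECONDS_PER_DAY
    return lo, hi
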