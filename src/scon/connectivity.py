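"""The simulated connectivity (S-CON) test for non-random event timing.

Given release events at offsets :math:`T_1 \\le \\dots \\le T_n` inside an
analysis window of length :math:`W`, the *connectivity* of event ``i`` is
the number of later events arriving within the following ``conn_interval_s``
seconds (30 s by default); the test statistic is the window-average
connectivity.  The null hypothesis of completely random timing is
simulated by placing ``n`` integers uniformly (with replacement) on
``[1, W]``; the critical value is the 95th percentile of ``B = 1000``
simulated averages, and the null is rejected when the observed average is
*strictly* larger.

Connectivity counts truncate at the window edge — no events are borrowed
from the following window — and the null simulator has the same
truncation, so the comparison is unbiased.  Two events in the same second
are ordered by sort position and count toward each other with a lag of 0,
matching the ties the integer null placement can itself produce.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .events import AnalysisWindow, PartitionResult, partition_windows

logger = logging.getLogger(__name__)

#: Above this many events a draw is scored by per-row binary search rather
#: than an n x n broadcast (memory trade-off only; results are identical).
_BROADCAST_MAX_N = 64


@dataclass(frozen=True)
class SconConfig:
    """Parameters of the S-CON test.

    conn_interval_s
        Trailing span Δ within which later events count as connected.
    n_sim
        Number of random placements B used to build the null distribution.
    percentile
        Order of the empirical critical value (0.95 → the ⌈0.95·B⌉-th
        order statistic of the null draws).
    min_events
        Smallest window occupancy the test accepts (the statistic is
        pairwise, so 2 suffices).
    """

    conn_interval_s: int = 30
    n_sim: int = 1000
    percentile: float = 0.95
    seed: int | None = None
    min_events: int = 2

    def __post_init__(self) -> None:
        if self.conn_interval_s <= 0:
            raise ValueError("conn_interval_s must be positive")
        if self.n_sim < 1:
            raise ValueError("n_sim must be >= 1")
        if not 0.0 < self.percentile < 1.0:
            raise ValueError("percentile must be in (0, 1)")
        if self.min_events < 2:
            raise ValueError("min_events must be >= 2")


@dataclass(frozen=True)
class ConnectivityProfile:
    per_event: np.ndarray
    average: float


@dataclass(frozen=True)
class SconResult:
    """Full audit record of one window's test."""

    window: AnalysisWindow
    conn_interval_s: int
    observed_avg: float | None
    null_draws: np.ndarray | None = field(repr=False, default=None)
    critical_value: float | None = None
    reject: bool | None = None
    status: str = "tested"  # "tested" | "skipped_min_events"


def connectivity_counts(
    offsets: np.ndarray | Sequence[int], conn_interval_s: int
) -> ConnectivityProfile:
    """Per-event connectivity and its window average.

    ``per_event[i]`` counts the events at sort positions after ``i`` whose
    offset exceeds ``offsets[i]`` by at most ``conn_interval_s`` seconds
    (ties, lag 0, included).
    """
    t = np.asarray(offsets, dtype=np.int64)
    if t.size == 0:
        raise ValueError("connectivity of an empty window is undefined")
    if np.any(np.diff(t) < 0):
        raise ValueError("offsets must be sorted")
    hi = np.searchsorted(t, t + conn_interval_s, side="right")
    per_event = hi - np.arange(1, t.size + 1)
    return ConnectivityProfile(per_event=per_event.astype(np.int64),
                               average=float(per_event.mean()))


def _avg_connectivity_rows(sorted_rows: np.ndarray, conn_interval_s: int) -> np.ndarray:
    """Average connectivity of each row of a (B, n) sorted integer matrix.

    The average equals (# ordered pairs i<j with t_j - t_i <= Δ) / n.
    """
    B, n = sorted_rows.shape
    if n <= _BROADCAST_MAX_N:
        diff = sorted_rows[:, None, :] - sorted_rows[:, :, None]
        within = (diff <= conn_interval_s) & np.triu(np.ones((n, n), dtype=bool), k=1)
        pairs = within.sum(axis=(1, 2))
    else:
        pairs = np.empty(B, dtype=np.int64)
        cols = np.arange(1, n + 1)
        for b in range(B):
            row = sorted_rows[b]
            pairs[b] = (np.searchsorted(row, row + conn_interval_s, side="right")
                        - cols).sum()
    return pairs / n


def simulate_null(
    n_events: int,
    window_length_s: int,
    cfg: SconConfig = SconConfig(),
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Null distribution of the average connectivity.

    Each of the B draws places ``n_events`` integers independently and
    uniformly (with replacement) on ``[1, window_length_s]``, sorts them,
    and scores the average connectivity exactly as the observed data are
    scored.
    """
    if n_events < 2:
        raise ValueError("the null requires at least 2 events")
    if window_length_s <= cfg.conn_interval_s:
        raise ValueError("window length must exceed the connectivity interval")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(cfg.seed if rng is None else rng)
    draws = rng.integers(1, window_length_s + 1, size=(cfg.n_sim, n_events))
    draws.sort(axis=1)
    return _avg_connectivity_rows(draws, cfg.conn_interval_s)


def critical_value(null_draws: np.ndarray, percentile: float = 0.95) -> float:
    """Empirical percentile as the ⌈p·B⌉-th order statistic of the draws."""
    draws = np.asarray(null_draws, dtype=np.float64)
    if draws.size == 0:
        raise ValueError("no null draws")
    k = math.ceil(percentile * draws.size)
    return float(np.sort(draws)[k - 1])


def scon_test(
    window: AnalysisWindow,
    cfg: SconConfig = SconConfig(),
    rng: np.random.Generator | int | None = None,
) -> SconResult:
    """Test one window: reject iff observed average > critical value."""
    if window.n_events < cfg.min_events:
        return SconResult(window=window, conn_interval_s=cfg.conn_interval_s,
                          observed_avg=None, status="skipped_min_events")
    observed = connectivity_counts(window.offsets, cfg.conn_interval_s).average
    draws = simulate_null(window.n_events, window.length_s, cfg, rng)
    crit = critical_value(draws, cfg.percentile)
    return SconResult(window=window, conn_interval_s=cfg.conn_interval_s,
                      observed_avg=observed, null_draws=draws,
                      critical_value=crit, reject=observed > crit)


def _window_rng(master_seed: int, length_s: int, delta: int, start: int
                ) -> np.random.Generator:
    """Child generator keyed on (window, Δ) so results never depend on
    which other windows are analyzed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed), int(length_s),
                                int(delta), int(start)])
    )


def sweep(
    events: np.ndarray,
    window_lengths: Sequence[int],
    conn_intervals: Sequence[int],
    span: tuple[int, int],
    cfg: SconConfig = SconConfig(),
    master_seed: int = 0,
    min_events: int | None = None,
    gaps: Sequence[tuple[int, int]] = (),
) -> pd.DataFrame:
    """Rejection percentage across window lengths and connectivity intervals.

    For every (window length, Δ) pair the event series is partitioned,
    each window with enough events is tested, and the rejected fraction is
    tabulated — the machine analogue of the rejection-rate figure.
    Deterministic under ``master_seed``.
    """
    if not window_lengths or not conn_intervals:
        raise ValueError("window_lengths and conn_intervals must be non-empty")
    min_ev = cfg.min_events if min_events is None else min_events
    rows = []
    for length in window_lengths:
        part = partition_windows(events, length, span, min_events=min_ev, gaps=gaps)
        for delta in conn_intervals:
            if delta >= length:
                warnings.warn(
                    f"skipping Δ={delta}s >= window length {length}s",
                    stacklevel=2,
                )
                continue
            pair_cfg = SconConfig(conn_interval_s=delta, n_sim=cfg.n_sim,
                                  percentile=cfg.percentile, min_events=min_ev)
            n_rej = 0
            for w in part.windows:
                res = scon_test(w, pair_cfg,
                                _window_rng(master_seed, length, delta, w.start))
                n_rej += bool(res.reject)
            n_win = part.n_analyzed
            rows.append({
                "window_length_s": length,
                "conn_interval_s": delta,
                "n_windows": n_win,
                "n_rejected": n_rej,
                "pct_rejected": 100.0 * n_rej / n_win if n_win else float("nan"),
            })
            logger.info("sweep W=%ds Δ=%ds: %d/%d rejected", length, delta,
                        n_rej, n_win)
    return pd.DataFrame(rows)
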