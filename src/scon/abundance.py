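"""Abundance control: do event counts merely track fish biomass?

Event counts per 30-min interval are regressed on the summed
surface-integrated backscattering coefficient (SA, the echo-integration
biomass proxy), both natural-log transformed, with AR(1)-correlated
errors.  The fit is iterated feasible GLS: estimate the lag-1 residual
autocorrelation, Prais-Winsten-transform the data, refit, and repeat to
convergence.  Reported alongside the slope is the F test (1, n-2 df) and
a variance-explained summary — GLS has no canonical R², so the convention
here is the squared Pearson correlation between fitted and observed
response.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

SECONDS_PER_DAY = 86_400


@dataclass(frozen=True)
class GlsFit:
    """Result of the log-log GLS with AR(1) errors."""

    slope: float
    intercept: float
    phi: float
    f_stat: float
    df: tuple[int, int]
    p_value: float
    var_explained: float
    n_used: int
    n_dropped: int
    n_iter: int

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["df"] = list(self.df)
        return d


def aggregate_counts(
    events: np.ndarray | Sequence[int],
    span: tuple[int, int],
    grid_s: int = 1800,
) -> pd.Series:
    """Event counts on a regular grid aligned to midnight UTC.

    Cells are half-open ``[start, start + grid_s)``: an event on the exact
    boundary second belongs to the later interval.  Counts conserve the
    total number of events in span.
    """
    if grid_s <= 0:
        raise ValueError("grid_s must be positive")
    t = np.asarray(events, dtype=np.int64)
    lo = (int(span[0]) // SECONDS_PER_DAY) * SECONDS_PER_DAY
    hi = int(span[1])
    if t.size and (t.min() < lo or t.max() >= hi):
        raise ValueError("events outside span")
    edges = np.arange(lo, hi + grid_s, grid_s, dtype=np.int64)
    counts, _ = np.histogram(t, bins=edges)
    return pd.Series(counts.astype(np.int64), index=edges[:-1], name="n_events")


def _prais_winsten(y: np.ndarray, x: np.ndarray, phi: float
                   ) -> tuple[np.ndarray, np.ndarray]:
    """AR(1)-whitening transform keeping the first observation."""
    X = sm.add_constant(x)
    w0 = np.sqrt(1.0 - phi**2)
    y_t = np.concatenate(([w0 * y[0]], y[1:] - phi * y[:-1]))
    X_t = np.vstack((w0 * X[0], X[1:] - phi * X[:-1]))
    return y_t, X_t


def fit_gls_ar1(
    series: pd.DataFrame,
    phi: float | None = None,
    zero_policy: str = "drop",
    tol: float = 1e-8,
    max_iter: int = 100,
) -> GlsFit:
    """Fit ``log(n_events) ~ log(sa)`` with AR(1)-correlated errors.

    ``series`` needs columns ``n_events`` and ``sa``.  Rows where either
    is zero (or missing) are dropped before the log transform under the
    default ``zero_policy="drop"``; ``"offset"`` instead adds 1 to both
    variables and keeps every finite row.  ``phi=None`` profiles the AR(1)
    parameter by iterated feasible GLS; a fixed ``phi`` (e.g. 0, which
    reproduces OLS exactly) skips the iteration.
    """
    if not {"n_events", "sa"} <= set(series.columns):
        raise ValueError("series must have columns 'n_events' and 'sa'")
    n_col = series["n_events"].to_numpy(dtype=np.float64)
    sa = series["sa"].to_numpy(dtype=np.float64)
    finite = np.isfinite(n_col) & np.isfinite(sa)
    if zero_policy == "drop":
        keep = finite & (n_col > 0) & (sa > 0)
        y, x = np.log(n_col[keep]), np.log(sa[keep])
    elif zero_policy == "offset":
        keep = finite
        y, x = np.log1p(n_col[keep]), np.log1p(sa[keep])
    else:
        raise ValueError(f"unknown zero_policy: {zero_policy!r}")
    n_dropped = int(len(series) - keep.sum())
    n = y.size
    if n < 10:
        raise ValueError(f"only {n} usable rows after dropping zeros; need >= 10")
    logger.info("fit_gls_ar1: %d rows used, %d dropped", n, n_dropped)

    if phi is not None:
        phi_hat, n_iter = float(phi), 0
        y_t, X_t = _prais_winsten(y, x, phi_hat)
        res = sm.OLS(y_t, X_t).fit()
    else:
        phi_hat, n_iter = 0.0, 0
        res = None
        for n_iter in range(1, max_iter + 1):
            y_t, X_t = _prais_winsten(y, x, phi_hat)
            res = sm.OLS(y_t, X_t).fit()
            # residuals on the original scale drive the AR(1) update
            resid = y - (res.params[0] + res.params[1] * x)
            denom = float(resid @ resid)
            phi_new = float(resid[1:] @ resid[:-1]) / denom if denom else 0.0
            phi_new = float(np.clip(phi_new, -0.999, 0.999))
            if abs(phi_new - phi_hat) < tol:
                phi_hat = phi_new
                break
            phi_hat = phi_new
        else:
            raise RuntimeError(
                f"AR(1) profiling did not converge in {max_iter} iterations "
                f"(last phi={phi_hat:.6f})"
            )

    intercept, slope = (float(res.params[0]), float(res.params[1]))
    t_slope = float(res.tvalues[1])
    f_stat = t_slope**2
    df = (1, n - 2)
    p_value = float(stats.f.sf(f_stat, *df))
    fitted = intercept + slope * x
    r = np.corrcoef(fitted, y)[0, 1] if np.std(fitted) > 0 else 0.0
    return GlsFit(slope=slope, intercept=intercept, phi=phi_hat,
                  f_stat=f_stat, df=df, p_value=p_value,
                  var_explained=float(r**2), n_used=n, n_dropped=n_dropped,
                  n_iter=n_iter)
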