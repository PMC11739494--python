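"""Time-series layer: STL decomposition of PS series, piecewise slopes
around a drought breakpoint, Kendall trend tests, intra-annual isotope
variance, and the radiocarbon (F14C) vs PS rank correlation.

Quarterly PS series are placed on a regular calendar-quarter grid (multiple
samples per well-quarter averaged, gaps left missing).  The STL settings
default to the quadruple used for quarterly groundwater series: period 4,
seasonal window 5, seasonal and trend degree 1.
"""
from __future__ import annotations

import dataclasses
import datetime as _dt
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.tsa.seasonal import STL

from .errors import ContractViolationError, DegenerateInputError, InsufficientDataError


@dataclasses.dataclass(frozen=True)
class STLParams:
    n_p: int = 4          # periods per cycle (quarterly)
    s_window: int = 5     # seasonal LOESS window
    t_degree: int = 1
    s_degree: int = 1


@dataclasses.dataclass
class STLComponents:
    index: pd.PeriodIndex
    trend: pd.Series
    seasonal: pd.Series
    remainder: pd.Series  # NaN at missing input points
    observed: pd.Series


def quarterly_series(dates: Sequence[_dt.date], values: Sequence[float]) -> pd.Series:
    """Average values onto a regular calendar-quarter grid; gaps are NaN."""
    s = pd.Series(np.asarray(values, float),
                  index=pd.PeriodIndex(pd.to_datetime(list(dates)), freq="Q"))
    grouped = s.groupby(level=0).mean()
    full = pd.period_range(grouped.index.min(), grouped.index.max(), freq="Q")
    return grouped.reindex(full)


def stl_decompose(series: pd.Series, params: STLParams = STLParams()) -> STLComponents:
    """Seasonal-trend decomposition by LOESS of a regular quarterly series.

    Missing values are linearly interpolated (edges extended) before the
    decomposition; at missing points the trend and seasonal components are
    the smoothed interpolants and the remainder is NaN.  The additive
    identity trend + seasonal + remainder = observed holds exactly at every
    non-missing point.
    """
    y = series.astype(float)
    if y.size < 3 * params.n_p:
        raise InsufficientDataError(
            f"STL needs >= {3 * params.n_p} quarterly points, got {y.size}")
    observed = y.copy()
    filled = y.interpolate(limit_direction="both")
    if filled.isna().any():
        raise DegenerateInputError("series is entirely missing")
    res = STL(filled.to_numpy(), period=params.n_p, seasonal=params.s_window,
              seasonal_deg=params.s_degree, trend_deg=params.t_degree,
              robust=False).fit()
    trend = pd.Series(res.trend, index=y.index)
    seasonal = pd.Series(res.seasonal, index=y.index)
    remainder = observed - trend - seasonal  # NaN where observed is NaN
    return STLComponents(index=y.index, trend=trend, seasonal=seasonal,
                         remainder=remainder, observed=observed)


def _years(times) -> np.ndarray:
    """Times as float years (accepts dates, Timestamps, Periods or numbers)."""
    arr = list(times)
    if len(arr) and isinstance(arr[0], pd.Period):
        arr = [p.to_timestamp() for p in arr]
    if len(arr) and isinstance(arr[0], (_dt.date, _dt.datetime, pd.Timestamp)):
        ts = pd.to_datetime(arr)
        epoch = pd.Timestamp("2000-01-01")
        return np.array([(t - epoch).days for t in ts], float) / 365.25
    return np.asarray(arr, dtype=float)


def linear_trend(times, values) -> tuple[float, float, float]:
    """OLS slope (units per year), intercept, and two-sided p-value."""
    x = _years(times)
    y = np.asarray(values, dtype=float)
    ok = ~np.isnan(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise InsufficientDataError("linear trend needs >=3 points")
    if np.ptp(x) == 0:
        raise DegenerateInputError("all time points identical")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.pvalue)


def piecewise_slopes(times, values, break_date) -> tuple[float, float, float]:
    """Independent OLS slopes before and after a supplied breakpoint.

    The partition is [start, break) and [break, end]; returns
    (slope_pre, slope_post, slope_post / slope_pre).
    """
    x = _years(times)
    xb = _years([break_date])[0]
    y = np.asarray(values, dtype=float)
    pre = x < xb
    post = ~pre
    ok = ~np.isnan(y)
    if (pre & ok).sum() < 3 or (post & ok).sum() < 3:
        raise InsufficientDataError(
            "piecewise slopes need >=3 points on each side of the breakpoint")
    s_pre, _, _ = linear_trend(x[pre], y[pre])
    s_post, _, _ = linear_trend(x[post], y[post])
    ratio = s_post / s_pre if s_pre != 0 else float("inf")
    return s_pre, s_post, ratio


def kendall_tau_test(x, y) -> tuple[float, float]:
    """Kendall tau-b with tie correction, two-sided p.

    Exact p for n <= 10 without ties, normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise InsufficientDataError("Kendall test needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("tau undefined for all-tied input")
    n = x.size
    no_ties = (np.unique(x).size == n) and (np.unique(y).size == n)
    method = "exact" if (n <= 10 and no_ties) else "asymptotic"
    res = stats.kendalltau(x, y, variant="b", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclasses.dataclass(frozen=True)
class VarianceRecord:
    well: str
    year: int
    variance: float  # per-mil squared
    n: int


def intra_annual_variance(observations: pd.DataFrame
                          ) -> tuple[list[VarianceRecord], dict[str, tuple[float, float]]]:
    """Per well-year sample variance of delta-18O and per-well Kendall trend.

    ``observations`` needs columns well, date, delta18O.  Well-years with
    fewer than 2 observations are dropped.  The variance is the unbiased
    sample variance sum((x - mean)^2) / (n - 1).  Returns the variance
    records and, per well with >=3 year points, (tau, p) of variance vs year.
    """
    df = observations.copy()
    df["year"] = pd.to_datetime(df["date"]).dt.year
    records: list[VarianceRecord] = []
    for (well, year), grp in df.groupby(["well", "year"], sort=True):
        if len(grp) < 2:
            continue
        records.append(VarianceRecord(
            well=str(well), year=int(year),
            variance=float(np.var(grp["delta18O"].to_numpy(float), ddof=1)),
            n=len(grp)))
    trends: dict[str, tuple[float, float]] = {}
    by_well: dict[str, list[VarianceRecord]] = {}
    for r in records:
        by_well.setdefault(r.well, []).append(r)
    for well, recs in by_well.items():
        if len(recs) >= 3:
            years = [r.year for r in recs]
            variances = [r.variance for r in recs]
            try:
                trends[well] = kendall_tau_test(years, variances)
            except DegenerateInputError:
                trends[well] = (0.0, 1.0)
    return records, trends


@dataclasses.dataclass(frozen=True)
class F14CRecord:
    sample_id: str
    f14c: float  # fraction modern carbon


def correlate_f14c(ps_records, f14c_records, subset: Optional[set] = None,
                   method: str = "spearman") -> tuple[float, float, int]:
    """Rank correlation between mean PS and F14C joined on sample_id.

    ``subset``, when given, restricts to sample_ids in it (supports e.g. an
    oxic-wells-only re-test).  Returns (rho, two-sided p, n pairs).
    """
    f14c_map = {r.sample_id: r.f14c for r in f14c_records}
    pairs = [(r.mean_ps, f14c_map[r.sample_id]) for r in ps_records
             if r.sample_id in f14c_map
             and (subset is None or r.sample_id in subset)]
    if len(pairs) < 5:
        raise InsufficientDataError(
            f"F14C correlation needs >=5 matched pairs, got {len(pairs)}")
    ps_vals, f_vals = zip(*pairs)
    if method == "spearman":
        rho, p = stats.spearmanr(ps_vals, f_vals)
    elif method == "kendall":
        rho, p = kendall_tau_test(np.asarray(ps_vals), np.asarray(f_vals))
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(rho), float(p), len(pairs)
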