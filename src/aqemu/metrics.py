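"""Pollutant exposure metrics.

* annual mean (PM2.5, μg m⁻³);
* 6mDM8h — the chronic ozone metric: for every day the maximum of the 24
  trailing 8-hour rolling means anchored at each start hour, then 12
  six-month means of those daily maxima (one window starting at each
  calendar month, wrapping within the year by default), and finally the
  maximum of the 12;
* population-weighted exposure over any cell subset;
* the ppb ↔ μg m⁻³ ozone standard conversion (1 ppb ≈ 2 μg m⁻³).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd


def annual_mean(values) -> float:
    """Arithmetic mean of the available hourly values."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty series")
    return float(v.mean())


def _hourly_index(values, timestamps, year: int):
    if isinstance(values, pd.Series):
        if timestamps is None and isinstance(values.index, pd.DatetimeIndex):
            timestamps = values.index
        values = values.to_numpy()
    values = np.asarray(values, dtype=float)
    if timestamps is None:
        timestamps = pd.date_range(f"{year}-01-01", periods=values.size, freq="h")
    else:
        timestamps = pd.DatetimeIndex(timestamps)
        if len(timestamps) != values.size:
            raise ValueError("timestamps and values differ in length")
        if not timestamps.is_monotonic_increasing or timestamps.has_duplicates:
            raise ValueError("timestamps must be strictly increasing")
        step = np.diff(timestamps.asi8)
        if (step != 3_600_000_000_000).any():
            warnings.warn("gaps in hourly series", stacklevel=3)
    return values, timestamps


def sixm_dm8h(values, timestamps=None, year: int = 2015, wrap: bool = True) -> float:
    """Maximum 6-monthly mean of the daily maximum 8-hour ozone mean (ppb).

    Each day contributes the maximum over its 24 trailing 8-hour windows
    (windows may extend into the next day; the final windows of the year
    are truncated at the series end). Twelve 6-month windows start at each
    calendar month; with ``wrap=True`` (default) windows past July wrap to
    the start of the same year, otherwise they are truncated at December.
    """
    values, ts = _hourly_index(values, timestamps, year)
    if values.size < 24:
        raise ValueError("need at least one complete day of hourly values")

    # trailing 8-h rolling mean anchored at each hour, truncated at the end
    n = values.size
    csum = np.concatenate([[0.0], np.cumsum(values)])
    end = np.minimum(np.arange(n) + 8, n)
    win = (csum[end] - csum[np.arange(n)]) / (end - np.arange(n))

    day = pd.Series(win, index=ts)
    daily_max = day.resample("D").max().dropna()
    month = daily_max.index.month.to_numpy()

    means = []
    for m0 in range(1, 13):
        sel_months = [(m0 - 1 + j) % 12 + 1 for j in range(6)]
        if not wrap:
            sel_months = [m for m in sel_months if m >= m0]
        mask = np.isin(month, sel_months)
        if mask.any():
            means.append(daily_max.to_numpy()[mask].mean())
    return float(max(means))


def population_weighted(values, population, subset=None) -> float:
    """Σ Pᵢ·Cᵢ / Σ Pᵢ over the selected cells."""
    c = np.asarray(values, dtype=float)
    p = np.asarray(population, dtype=float)
    if subset is not None:
        c, p = c[subset], p[subset]
    if c.size == 0 or p.sum() <= 0:
        raise ValueError("subset empty or zero total population")
    return float(np.average(c, weights=p))


def ugm3_to_ppb(value: float) -> float:
    """Ozone standard conversion: 1 ppb ≈ 2 μg m⁻³."""
    v = np.asarray(value, dtype=float)
    if (v < 0).any():
        raise ValueError("concentration must be non-negative")
    out = v / 2.0
    return float(out) if out.ndim == 0 else out
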