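"""Thermal time: growing degree day (GDD) accumulation after full bloom.

All downstream growth analysis uses accumulated GDD as the physiological
time axis.  Daily GDD is the mean of the hourly mean temperatures minus a
base temperature, after restricting hourly values to the interval
[base, upper cutoff] (default 4.5-35 degC).  Accumulation starts at the
full-bloom date; days before bloom contribute nothing.

Temperature series are represented as :class:`pandas.Series` with a
``DatetimeIndex`` (strictly increasing) and temperatures in degC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_BASE_TEMP = 4.5
"""Base temperature in degC below which no thermal time accrues."""

DEFAULT_UPPER_CUTOFF = 35.0
"""Upper cutoff in degC above which no additional thermal time accrues."""

#: Minimum number of valid hourly values required to compute a daily mean.
MIN_HOURS_PER_DAY = 18


def _validate_series(series: pd.Series) -> pd.Series:
    if not isinstance(series, pd.Series) or not isinstance(
        series.index, pd.DatetimeIndex
    ):
        raise TypeError("temperature series must be a pandas Series with a DatetimeIndex")
    if len(series) == 0:
        raise ValueError("temperature series is empty")
    if not series.index.is_monotonic_increasing or series.index.has_duplicates:
        raise ValueError("temperature timestamps must be strictly increasing")
    if not np.isfinite(series.to_numpy(dtype=float)).all():
        raise ValueError("temperature series contains non-finite values")
    return series.astype(float)


def hourly_means(series: pd.Series) -> pd.Series:
    """Aggregate a (possibly sub-hourly) temperature record to hourly means.

    Field loggers commonly record every 30 min or more often; the GDD
    definition works on hourly mean temperatures, so sub-hourly records are
    averaged within each clock hour first.  An already-hourly series passes
    through unchanged.  Hours spanned by the record but containing no
    observation come back as NaN (missing) and are flagged in the log.
    """
    series = _validate_series(series)
    out = series.resample("1h").mean()
    n_missing = int(out.isna().sum())
    if n_missing:
        logger.warning("hourly_means: %d hour(s) without any record", n_missing)
    return out


def daily_gdd(
    hourly_temps: "np.ndarray | list[float] | pd.Series",
    base_temp: float = DEFAULT_BASE_TEMP,
    upper_cutoff: float = DEFAULT_UPPER_CUTOFF,
    cutoff_mode: str = "clamp",
    date: object = None,
) -> float:
    """Daily GDD from one day's hourly mean temperatures.

    Each hourly value is clamped into ``[base_temp, upper_cutoff]``
    (``cutoff_mode="clamp"``, the default) or, alternatively, hours outside
    that range are discarded (``cutoff_mode="discard"``).  The result is
    ``mean(processed hours) - base_temp``, never negative.

    Parameters
    ----------
    hourly_temps
        Hourly mean temperatures (degC) for a single day; NaN marks a
        missing hour.
    date
        Optional label used in error messages only.
    """
    if base_temp >= upper_cutoff:
        raise ValueError("base_temp must be below upper_cutoff")
    if cutoff_mode not in ("clamp", "discard"):
        raise ValueError(f"unknown cutoff_mode {cutoff_mode!r}")
    temps = np.asarray(hourly_temps, dtype=float)
    temps = temps[np.isfinite(temps)]
    if temps.size == 0:
        raise ValueError(f"no valid hourly temperatures for day {date!r}")
    if cutoff_mode == "clamp":
        processed = np.clip(temps, base_temp, upper_cutoff)
    else:
        processed = temps[(temps >= base_temp) & (temps <= upper_cutoff)]
        if processed.size == 0:
            # every hour outside range: a fully cold (or hot-clipped) day
            # contributes nothing rather than erroring
            return 0.0
    return float(np.mean(processed) - base_temp)


@dataclass
class ThermalTimeAxis:
    """Cumulative GDD per calendar day, anchored at the full-bloom date.

    ``cumulative_gdd[i]`` is the thermal time accumulated from bloom through
    the *end* of ``dates[i]``; measurement dates therefore map to
    end-of-day cumulative GDD.
    """

    dates: pd.DatetimeIndex
    daily_gdd: np.ndarray
    cumulative_gdd: np.ndarray
    bloom_date: pd.Timestamp
    base_temp: float = DEFAULT_BASE_TEMP
    upper_cutoff: float = DEFAULT_UPPER_CUTOFF

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        self.daily_gdd = np.asarray(self.daily_gdd, dtype=float)
        self.cumulative_gdd = np.asarray(self.cumulative_gdd, dtype=float)
        self.bloom_date = pd.Timestamp(self.bloom_date).normalize()
        span = self.upper_cutoff - self.base_temp
        if np.any(self.daily_gdd < -1e-12) or np.any(self.daily_gdd > span + 1e-12):
            raise ValueError("daily_gdd outside [0, upper_cutoff - base_temp]")
        if np.any(np.diff(self.cumulative_gdd) < -1e-12):
            raise ValueError("cumulative_gdd must be non-decreasing")

    def gdd_at(self, date: object) -> float:
        """Cumulative GDD at the end of ``date`` (0 before bloom)."""
        day = pd.Timestamp(date).normalize()
        if day < self.dates[0] or day > self.dates[-1]:
            raise ValueError(
                f"date {day.date()} outside thermal axis coverage "
                f"({self.dates[0].date()} .. {self.dates[-1].date()})"
            )
        idx = self.dates.get_loc(day)
        return float(self.cumulative_gdd[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "date": self.dates.strftime("%Y-%m-%d"),
                "daily_gdd": self.daily_gdd,
                "cumulative_gdd": self.cumulative_gdd,
            }
        )


def accumulate_gdd(
    series: pd.Series,
    bloom_date: object,
    base_temp: float = DEFAULT_BASE_TEMP,
    upper_cutoff: float = DEFAULT_UPPER_CUTOFF,
    cutoff_mode: str = "clamp",
    min_hours: int = MIN_HOURS_PER_DAY,
) -> ThermalTimeAxis:
    """Accumulate daily GDD from ``bloom_date`` onwards.

    The input may be sub-hourly; it is first reduced to hourly means.  Days
    with fewer than ``min_hours`` valid hours raise (silently averaging a
    sparsely covered day would bias its mean).  Days before bloom appear on
    the axis with their daily GDD but contribute 0 to the cumulative sum.
    """
    hourly = hourly_means(series)
    bloom = pd.Timestamp(bloom_date).normalize()
    first_day = hourly.index[0].normalize()
    last_day = hourly.index[-1].normalize()
    if bloom < first_day or bloom > last_day:
        raise ValueError(
            f"bloom date {bloom.date()} outside weather coverage "
            f"({first_day.date()} .. {last_day.date()})"
        )
    days = []
    daily = []
    for day, group in hourly.groupby(hourly.index.normalize()):
        vals = group.to_numpy(dtype=float)
        n_valid = int(np.isfinite(vals).sum())
        if n_valid < min_hours:
            raise ValueError(
                f"day {pd.Timestamp(day).date()} has only {n_valid} valid "
                f"hour(s); at least {min_hours} required"
            )
        days.append(pd.Timestamp(day))
        daily.append(daily_gdd(vals, base_temp, upper_cutoff, cutoff_mode, date=day))
    dates = pd.DatetimeIndex(days)
    daily_arr = np.asarray(daily, dtype=float)
    contributing = np.where(dates >= bloom, daily_arr, 0.0)
    cumulative = np.cumsum(contributing)
    return ThermalTimeAxis(
        dates=dates,
        daily_gdd=daily_arr,
        cumulative_gdd=cumulative,
        bloom_date=bloom,
        base_temp=base_temp,
        upper_cutoff=upper_cutoff,
    )


def gdd_at(axis: ThermalTimeAxis, date: object) -> float:
    """Functional form of :meth:`ThermalTimeAxis.gdd_at`."""
    return axis.gdd_at(date)
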