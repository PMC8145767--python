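"""Hourly growing degree-day accumulation with cardinal-temperature capping.

Thermal time is accumulated hour by hour: each hourly temperature T_h
contributes

    0             if T_h <= T_b
    T_h - T_b     if T_b < T_h <= T_u
    T_u - T_b     if T_h > T_u

degree-hours, where T_b is the base temperature (development stops at or
below it) and T_u the optional upper threshold (accumulation saturates at
or above it).  A day's growing degree-hours (GDH) are summed over its 24
records and divided by 24 to give that day's growing degree days (GDD);
cumulative GDD over a phenological interval is the running sum of daily
GDD.  Dividing per day rather than once at the end is algebraically
identical but exposes a meaningful daily series for forecasting.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .weather_io import HourlyTemperatureSeries

__all__ = [
    "ThermalThresholds",
    "GddAccumulation",
    "MissingDataError",
    "hourly_contribution",
    "hourly_contribution_array",
    "daily_gdd",
    "accumulate",
    "gdd_between_stages",
]


class MissingDataError(ValueError):
    """The series does not fully cover a requested day or interval."""


@dataclass(frozen=True)
class ThermalThresholds:
    """Cardinal temperature pair: base T_b and optional upper threshold T_u.

    ``t_upper=None`` disables capping, which is how base-temperature scans
    run before an upper threshold has been selected.
    """

    t_base: float
    t_upper: float | None = None

    def __post_init__(self) -> None:
        if self.t_upper is not None and not self.t_base < self.t_upper:
            raise ValueError(
                f"t_base ({self.t_base}) must be strictly below t_upper ({self.t_upper})"
            )

    @property
    def cap(self) -> float:
        """Maximum possible daily GDD, T_u - T_b (inf when uncapped)."""
        return np.inf if self.t_upper is None else self.t_upper - self.t_base


@dataclass(frozen=True)
class GddAccumulation:
    """Per-day GDH/GDD contributions and their running cumulative sum."""

    start_date: date
    end_date: date
    daily: pd.DataFrame  # columns: date, gdh, gdd, cumulative
    thresholds: ThermalThresholds

    @property
    def total(self) -> float:
        return float(self.daily["cumulative"].iloc[-1])

    @property
    def n_days(self) -> int:
        return len(self.daily)

    def to_csv(self, path) -> None:
        self.daily.to_csv(path, index=False)


def hourly_contribution(t_h: float, thresholds: ThermalThresholds) -> float:
    """Degree-hours contributed by a single hourly temperature."""
    if t_h <= thresholds.t_base:
        return 0.0
    if thresholds.t_upper is not None and t_h > thresholds.t_upper:
        return thresholds.t_upper - thresholds.t_base
    return t_h - thresholds.t_base


def hourly_contribution_array(temps: np.ndarray, thresholds: ThermalThresholds) -> np.ndarray:
    """Vectorised :func:`hourly_contribution` over an array of temperatures."""
    excess = np.asarray(temps, dtype=float) - thresholds.t_base
    return np.clip(excess, 0.0, thresholds.cap)


def _day_temps(series: HourlyTemperatureSeries, day: date) -> np.ndarray:
    vals = series.slice_dates(day, day)
    if len(vals) != 24:
        raise MissingDataError(
            f"{series.site_label}: {day} has {len(vals)} hourly records, need 24"
        )
    return vals.to_numpy(dtype=float)


def daily_gdd(
    series: HourlyTemperatureSeries, day: date, thresholds: ThermalThresholds
) -> float:
    """GDD of one calendar day: sum of its 24 hourly contributions / 24."""
    return float(hourly_contribution_array(_day_temps(series, day), thresholds).sum() / 24.0)


def accumulate(
    series: HourlyTemperatureSeries,
    start: date,
    end: date,
    thresholds: ThermalThresholds,
) -> GddAccumulation:
    """Daily and cumulative GDD for every date in [start, end] inclusive.

    Raises :class:`MissingDataError` if any day in the interval lacks its
    24 hourly records.
    """
    if start > end:
        raise ValueError(f"start {start} after end {end}")
    vals = series.slice_dates(start, end)
    n_days = (end - start).days + 1
    if len(vals) != 24 * n_days:
        # locate the first incomplete day for the error message
        counts = vals.groupby(vals.index.normalize()).size()
        for k in range(n_days):
            d = start + timedelta(days=k)
            if counts.get(pd.Timestamp(d), 0) != 24:
                raise MissingDataError(
                    f"{series.site_label}: {d} has "
                    f"{int(counts.get(pd.Timestamp(d), 0))} hourly records, need 24"
                )
        raise MissingDataError(f"{series.site_label}: interval {start}..{end} incomplete")
    gdh = (
        hourly_contribution_array(vals.to_numpy(dtype=float), thresholds)
        .reshape(n_days, 24)
        .sum(axis=1)
    )
    gdd = gdh / 24.0
    daily = pd.DataFrame(
        {
            "date": [start + timedelta(days=k) for k in range(n_days)],
            "gdh": gdh,
            "gdd": gdd,
            "cumulative": np.cumsum(gdd),
        }
    )
    return GddAccumulation(start_date=start, end_date=end, daily=daily, thresholds=thresholds)


def gdd_between_stages(
    series: HourlyTemperatureSeries,
    phen,
    from_stage: str,
    to_stage: str,
    thresholds: ThermalThresholds,
) -> tuple[float, int]:
    """GDD and day count between two phenological stages of one season.

    The interval convention counts the start stage's date in full and
    excludes the end stage's date, so stage-wise GDD and days are additive:
    (bud_break→bloom) + (bloom→harvest) = (bud_break→harvest) exactly.

    Returns ``(gdd, days)`` with ``days = to_date - from_date``.
    """
    from .phenology import StageError  # local import to avoid cycle

    from_date = phen.stage_date(from_stage)
    to_date = phen.stage_date(to_stage)
    if from_date is None or to_date is None:
        raise StageError(
            f"season {phen.season}: stage dates {from_stage!r} -> {to_stage!r} not both present"
        )
    if not from_date < to_date:
        raise StageError(
            f"season {phen.season}: {from_stage} ({from_date}) not before {to_stage} ({to_date})"
        )
    acc = accumulate(series, from_date, to_date - timedelta(days=1), thresholds)
    return acc.total, (to_date - from_date).days
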