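"""Reading, validating, repairing and summarising hourly temperature series.

Hourly air temperature is the raw material of every thermal-time
computation in this package.  Station exports are rarely pristine, so the
reader validates timestamps and plausibility, :func:`fill_gaps` repairs
short outages by linear interpolation, and :func:`build_average_year`
collapses several historical years into a single 365 x 24 reference year
(the "average year" used to project a coming season's harvest date).

Timestamps are naive local time throughout; no time-zone arithmetic is
performed, which keeps hour counting free of DST artefacts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import date, datetime

import numpy as np
import pandas as pd

__all__ = [
    "WeatherFormatError",
    "WeatherValidationError",
    "CoverageError",
    "UnrecoverableGapError",
    "HourlyTemperatureSeries",
    "DailyTemperatureSummary",
    "ReferenceYear",
    "read_hourly_csv",
    "write_hourly_csv",
    "fill_gaps",
    "daily_stats",
    "build_average_year",
    "read_reference_year_csv",
    "write_reference_year_csv",
]

DEFAULT_PLAUSIBILITY = (-30.0, 60.0)


class WeatherFormatError(ValueError):
    """A row of a weather CSV could not be parsed."""


class WeatherValidationError(ValueError):
    """Parsed data violate a series invariant (duplicates, implausible values)."""


class CoverageError(ValueError):
    """A required (month, day, hour) slot or date interval is not covered."""


class UnrecoverableGapError(ValueError):
    """A gap longer than the permitted maximum was found."""


@dataclass(frozen=True)
class HourlyTemperatureSeries:
    """An ordered hourly air-temperature record for one site.

    Parameters
    ----------
    site_label:
        Free-text identifier of the station / plot.
    data:
        Temperatures in deg C indexed by a naive local ``DatetimeIndex``.
    imputed:
        Boolean mask aligned with ``data``; True where the value was
        produced by gap interpolation rather than observed.
    """

    site_label: str
    data: pd.Series
    imputed: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not isinstance(self.data.index, pd.DatetimeIndex):
            raise WeatherValidationError("data must be indexed by timestamps")
        if len(self.data) < 24:
            raise WeatherValidationError(
                f"series {self.site_label!r} has {len(self.data)} records; need >= 24"
            )
        if not self.data.index.is_monotonic_increasing:
            raise WeatherValidationError("timestamps must be sorted ascending")
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()]
            raise WeatherValidationError(f"duplicate timestamps: {list(dupes[:3])} ...")
        if self.imputed is None:
            object.__setattr__(
                self, "imputed", pd.Series(False, index=self.data.index)
            )

    def __len__(self) -> int:
        return len(self.data)

    @property
    def start(self) -> datetime:
        return self.data.index[0].to_pydatetime()

    @property
    def end(self) -> datetime:
        return self.data.index[-1].to_pydatetime()

    def is_hourly_contiguous(self) -> bool:
        """True when consecutive timestamps are exactly one hour apart."""
        if len(self.data) < 2:
            return True
        deltas = np.diff(self.data.index.asi8)
        return bool(np.all(deltas == 3_600_000_000_000))

    def slice_dates(self, start: date, end: date) -> pd.Series:
        """Temperatures for calendar dates ``start`` .. ``end`` inclusive."""
        lo = pd.Timestamp(start)
        hi = pd.Timestamp(end) + pd.Timedelta(hours=23)
        return self.data.loc[lo:hi]


@dataclass(frozen=True)
class DailyTemperatureSummary:
    """Min / mean / max temperature of one complete (24-record) day."""

    date: date
    t_min: float
    t_mean: float
    t_max: float

    def __post_init__(self) -> None:
        if not (self.t_min <= self.t_mean <= self.t_max):
            raise WeatherValidationError(
                f"{self.date}: t_min <= t_mean <= t_max violated "
                f"({self.t_min}, {self.t_mean}, {self.t_max})"
            )


@dataclass(frozen=True)
class ReferenceYear:
    """A 365-day x 24-hour reference temperature year (Feb 29 excluded).

    ``values`` is indexed by a (month, day, hour) MultiIndex with exactly
    8760 entries.  ``kind`` records how the year was built: slot-wise
    ``average`` over historical years, an externally supplied ``tmy``
    (typical meteorological year), or a single ``observed`` year.
    """

    kind: str
    values: pd.Series

    _KINDS = ("average", "tmy", "observed")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise WeatherValidationError(f"kind must be one of {self._KINDS}")
        if len(self.values) != 8760:
            raise WeatherValidationError(
                f"reference year needs 8760 slots, got {len(self.values)}"
            )
        if self.values.index.has_duplicates:
            raise WeatherValidationError("duplicate (month, day, hour) slots")
        if self.values.isna().any():
            raise WeatherValidationError("reference year contains missing values")

    def day_temperatures(self, month: int, day: int) -> np.ndarray:
        """The 24 hourly temperatures of one (month, day) slot."""
        try:
            return self.values.loc[(month, day)].to_numpy(dtype=float)
        except KeyError:
            raise CoverageError(f"slot ({month:02d}-{day:02d}) absent") from None


def _slot_index() -> pd.MultiIndex:
    """(month, day, hour) index of a non-leap year in calendar order."""
    hours = pd.date_range("2001-01-01", "2001-12-31 23:00", freq="h")
    return pd.MultiIndex.from_arrays(
        [
            hours.month.astype("int64"),
            hours.day.astype("int64"),
            hours.hour.astype("int64"),
        ],
        names=["month", "day", "hour"],
    )


def read_hourly_csv(
    path,
    plausibility: tuple[float, float] = DEFAULT_PLAUSIBILITY,
    site_label: str | None = None,
) -> HourlyTemperatureSeries:
    """Read an hourly weather CSV with columns ``timestamp`` and ``temp_c``.

    Rows are sorted ascending by timestamp.  Unparseable rows raise
    :class:`WeatherFormatError` naming the offending line (1-based, header
    is line 1); duplicated timestamps and temperatures outside the
    plausibility window raise :class:`WeatherValidationError`.
    """
    raw = pd.read_csv(path, dtype=str)
    missing = {"timestamp", "temp_c"} - set(raw.columns)
    if missing:
        raise WeatherFormatError(f"{path}: missing columns {sorted(missing)}")

    ts = pd.to_datetime(raw["timestamp"], errors="coerce", format="ISO8601")
    if ts.isna().any():
        line = int(ts.index[ts.isna()][0]) + 2
        raise WeatherFormatError(
            f"{path}: unparseable timestamp at line {line}: {raw['timestamp'][line - 2]!r}"
        )
    temps = pd.to_numeric(raw["temp_c"], errors="coerce")
    if temps.isna().any():
        line = int(temps.index[temps.isna()][0]) + 2
        raise WeatherFormatError(
            f"{path}: unparseable temperature at line {line}: {raw['temp_c'][line - 2]!r}"
        )
    # to_numeric's fast parser is not correctly rounded; astype(float) is
    temps = raw["temp_c"].astype(float)

    if ts.duplicated().any():
        dupe = ts[ts.duplicated()].iloc[0]
        raise WeatherValidationError(f"{path}: duplicate timestamp {dupe}")

    lo, hi = plausibility
    bad = (temps < lo) | (temps > hi)
    if bad.any():
        line = int(temps.index[bad][0]) + 2
        raise WeatherValidationError(
            f"{path}: temperature {temps[line - 2]} degC outside [{lo}, {hi}] at line {line}"
        )

    data = pd.Series(temps.to_numpy(dtype=float), index=pd.DatetimeIndex(ts))
    data = data.sort_index()
    label = site_label if site_label is not None else str(path)
    return HourlyTemperatureSeries(site_label=label, data=data)


def write_hourly_csv(series: HourlyTemperatureSeries, path) -> None:
    """Write a series in the same dialect :func:`read_hourly_csv` consumes."""
    out = pd.DataFrame(
        {
            "timestamp": series.data.index.strftime("%Y-%m-%dT%H:%M:%S"),
            # repr keeps the float bit-identical through the round trip
            "temp_c": [repr(float(v)) for v in series.data.to_numpy()],
        }
    )
    out.to_csv(path, index=False)


def fill_gaps(series: HourlyTemperatureSeries, max_gap: int = 6) -> HourlyTemperatureSeries:
    """Linearly interpolate missing hours up to ``max_gap`` consecutive hours.

    The returned series has strictly hourly spacing; interpolated records
    are flagged in ``imputed``.  A gap longer than ``max_gap`` raises
    :class:`UnrecoverableGapError` listing the interval.  Idempotent: a
    contiguous series is returned unchanged.
    """
    if max_gap < 1:
        raise ValueError("max_gap must be >= 1")
    if series.is_hourly_contiguous():
        return series

    idx = series.data.index
    deltas = np.diff(idx.asi8) // 3_600_000_000_000
    too_long = np.nonzero(deltas > max_gap + 1)[0]
    if too_long.size:
        k = int(too_long[0])
        raise UnrecoverableGapError(
            f"gap of {int(deltas[k]) - 1} h between {idx[k]} and {idx[k + 1]} "
            f"exceeds max_gap={max_gap}"
        )
    full = pd.date_range(idx[0], idx[-1], freq="h")
    filled = series.data.reindex(full)
    imputed = filled.isna()
    filled = filled.interpolate(method="time", limit_area="inside")
    return HourlyTemperatureSeries(
        site_label=series.site_label,
        data=filled,
        imputed=series.imputed.reindex(full, fill_value=False) | imputed,
    )


def daily_stats(series: HourlyTemperatureSeries) -> list[DailyTemperatureSummary]:
    """Min / mean / max per complete day; incomplete days omitted with a warning."""
    by_day = series.data.groupby(series.data.index.normalize())
    out: list[DailyTemperatureSummary] = []
    for day, vals in by_day:
        if len(vals) != 24:
            warnings.warn(
                f"{series.site_label}: day {day.date()} has {len(vals)} records, omitted",
                stacklevel=2,
            )
            continue
        out.append(
            DailyTemperatureSummary(
                date=day.date(),
                t_min=float(vals.min()),
                t_mean=float(vals.mean()),
                t_max=float(vals.max()),
            )
        )
    return out


def build_average_year(series_list: list[HourlyTemperatureSeries]) -> ReferenceYear:
    """Slot-wise arithmetic mean over years -> an ``average`` reference year.

    Every (month, day, hour) slot must be covered by at least one input
    year; Feb 29 records are dropped.
    """
    if not series_list:
        raise CoverageError("need at least one input series")
    frames = []
    for s in series_list:
        idx = s.data.index
        keep = ~((idx.month == 2) & (idx.day == 29))
        d = s.data[keep]
        frames.append(
            pd.Series(
                d.to_numpy(),
                index=pd.MultiIndex.from_arrays(
                    [
                        d.index.month.astype("int64"),
                        d.index.day.astype("int64"),
                        d.index.hour.astype("int64"),
                    ],
                    names=["month", "day", "hour"],
                ),
            )
        )
    pooled = pd.concat(frames)
    means = pooled.groupby(level=[0, 1, 2]).mean()
    target = _slot_index()
    missing = target.difference(means.index)
    if len(missing):
        m, d, h = missing[0]
        raise CoverageError(
            f"{len(missing)} uncovered slots; first is ({m:02d}-{d:02d} {h:02d}:00)"
        )
    return ReferenceYear(kind="average", values=means.reindex(target))


def read_reference_year_csv(path, kind: str = "average") -> ReferenceYear:
    """Read a reference-year CSV with columns ``month,day,hour,temp_c``."""
    raw = pd.read_csv(path)
    need = {"month", "day", "hour", "temp_c"}
    if need - set(raw.columns):
        raise WeatherFormatError(f"{path}: missing columns {sorted(need - set(raw.columns))}")
    values = pd.Series(
        raw["temp_c"].to_numpy(dtype=float),
        index=pd.MultiIndex.from_arrays(
            [
                raw["month"].to_numpy(dtype="int64"),
                raw["day"].to_numpy(dtype="int64"),
                raw["hour"].to_numpy(dtype="int64"),
            ],
            names=["month", "day", "hour"],
        ),
    )
    return ReferenceYear(kind=kind, values=values.reindex(_slot_index()))


def write_reference_year_csv(year: ReferenceYear, path) -> None:
    out = year.values.rename("temp_c").reset_index()
    out.to_csv(path, index=False)
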