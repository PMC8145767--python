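"""Harvest-date forecasting from heat-unit requirements.

A cultivar's mean GDD requirement between bud break and ripening, once
established over historical seasons, predicts the coming harvest: starting
at bud break (inclusive), daily GDD are accumulated over observed weather
or over a reference year until the requirement is met; harvest is declared
at the end of the first day reaching it.  The calendar-day baseline —
bud break plus the historical mean cycle length — serves as the comparator
the GDD method must beat.

Deviations are reported as predicted minus observed (PHD − OHD) in signed
days; a method's accuracy is the mean absolute deviation rounded half-up
to whole days.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date, timedelta
from typing import Literal, Mapping, Sequence

import numpy as np

from .gdd import ThermalThresholds, accumulate, hourly_contribution_array
from .weather_io import HourlyTemperatureSeries, ReferenceYear

__all__ = [
    "NonConvergenceError",
    "HeatRequirement",
    "HarvestForecast",
    "round_half_up",
    "mean_requirement",
    "leave_current_out_requirement",
    "predict_harvest_gdd",
    "predict_harvest_calendar",
    "evaluate",
]

MAX_PROJECTION_DAYS = 400


class NonConvergenceError(ValueError):
    """The GDD requirement is not reached within the projection horizon."""


def round_half_up(x: float) -> int:
    """Round to the nearest integer with .5 going away from zero upward."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class HeatRequirement:
    """Mean heat (GDD) and cycle length over historical seasons of one site."""

    site: str
    from_stage: str
    to_stage: str
    per_season_gdd: tuple[float, ...]
    per_season_days: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.per_season_gdd:
            raise ValueError("need at least one season")
        if len(self.per_season_gdd) != len(self.per_season_days):
            raise ValueError("gdd and days lists must align")

    @property
    def mean_gdd(self) -> float:
        """Unrounded mean GDD requirement (degree-days)."""
        return float(np.mean(self.per_season_gdd))

    @property
    def mean_gdd_rounded(self) -> int:
        return round_half_up(self.mean_gdd)

    @property
    def mean_days_exact(self) -> float:
        return float(np.mean(self.per_season_days))

    @property
    def mean_days(self) -> int:
        """Cycle length for the calendar baseline, rounded half-up to days."""
        return round_half_up(self.mean_days_exact)


@dataclass(frozen=True)
class HarvestForecast:
    """Predicted vs observed harvest date for one season and method."""

    season: str
    method: Literal["gdd", "calendar"]
    predicted: date
    observed: date | None = None
    site: str = ""

    @property
    def deviation(self) -> int | None:
        """Signed PHD − OHD in days; None while the observation is pending."""
        if self.observed is None:
            return None
        return (self.predicted - self.observed).days


def mean_requirement(
    per_season_gdd: Sequence[float],
    per_season_days: Sequence[int],
    site: str = "open_field",
    from_stage: str = "bud_break",
    to_stage: str = "harvest",
) -> HeatRequirement:
    """Arithmetic-mean heat requirement and cycle length over seasons."""
    if len(per_season_gdd) < 1:
        raise ValueError("need at least one season")
    return HeatRequirement(
        site=site,
        from_stage=from_stage,
        to_stage=to_stage,
        per_season_gdd=tuple(float(g) for g in per_season_gdd),
        per_season_days=tuple(int(d) for d in per_season_days),
    )


def leave_current_out_requirement(
    per_season_gdd: Mapping[str, float],
    per_season_days: Mapping[str, int],
    target_season: str,
    exclude_target: bool = False,
    site: str = "open_field",
) -> HeatRequirement:
    """Requirement to apply to one target season.

    Default mode reproduces the historical practice of applying the full
    multi-season mean to every season (the target's own data included);
    ``exclude_target=True`` gives honest leave-one-out cross-validation.
    """
    seasons = sorted(per_season_gdd)
    if exclude_target:
        seasons = [s for s in seasons if s != target_season]
        if len(seasons) < 1:
            raise ValueError("exclude-target mode needs >= 2 seasons")
    return mean_requirement(
        [per_season_gdd[s] for s in seasons],
        [per_season_days[s] for s in seasons],
        site=site,
    )


def _reference_daily_gdd(
    reference: ReferenceYear, day: date, thresholds: ThermalThresholds
) -> float:
    # Feb 29 has no slot in a 365-day reference year: skipped (contributes 0).
    if day.month == 2 and day.day == 29:
        return 0.0
    temps = reference.day_temperatures(day.month, day.day)
    return float(hourly_contribution_array(temps, thresholds).sum() / 24.0)


def predict_harvest_gdd(
    reference: ReferenceYear | HourlyTemperatureSeries,
    bud_break: date,
    requirement: float,
    thresholds: ThermalThresholds,
    max_days: int = MAX_PROJECTION_DAYS,
) -> date:
    """First date whose cumulative GDD from bud break (inclusive) meets the requirement.

    Accumulation starts on the bud-break day itself and harvest is declared
    at the end of the first day on which the running total reaches
    ``requirement``.  A :class:`ReferenceYear` is traversed cyclically
    (projections may wrap past Dec 31); an observed series must cover the
    horizon day by day.  ``requirement=0`` returns bud break itself.
    """
    if requirement < 0:
        raise ValueError("requirement must be >= 0")
    total = 0.0
    for k in range(max_days):
        day = bud_break + timedelta(days=k)
        if isinstance(reference, ReferenceYear):
            total += _reference_daily_gdd(reference, day, thresholds)
        else:
            total += accumulate(reference, day, day, thresholds).total
        if total >= requirement:
            return day
    raise NonConvergenceError(
        f"requirement {requirement} GDD not reached within {max_days} days of {bud_break} "
        f"(accumulated {total:.1f})"
    )


def predict_harvest_calendar(bud_break: date, mean_days: int) -> date:
    """Calendar-day baseline: bud break plus the historical mean cycle length."""
    if mean_days < 0:
        raise ValueError("mean_days must be >= 0")
    return bud_break + timedelta(days=mean_days)


def evaluate(forecasts: Sequence[HarvestForecast]) -> tuple[dict[str, int], int]:
    """Per-season signed deviations and the method's accuracy in days.

    Accuracy = mean of |PHD − OHD| over seasons, rounded half-up to whole
    days.  Every forecast must carry an observed date.
    """
    if not forecasts:
        raise ValueError("no forecasts to evaluate")
    deviations: dict[str, int] = {}
    for f in forecasts:
        if f.observed is None:
            raise ValueError(f"season {f.season}: observed harvest date missing")
        deviations[f.season] = f.deviation  # type: ignore[assignment]
    accuracy = round_half_up(float(np.mean([abs(d) for d in deviations.values()])))
    return deviations, accuracy
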