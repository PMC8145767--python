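"""Synthetic hourly weather and thermally consistent phenology.

No weather or phenology data accompany the study this package's methods
address, so validation runs on simulated seasons with known ground truth.
The weather model is deliberately simple but keeps the features the
estimators care about:

* an annual sinusoid (coolest mid-January, warmest mid-July) around a
  site mean of 18.5 deg C, as at a coastal semiarid Mediterranean site;
* a diurnal sinusoid (coolest pre-dawn, warmest mid-afternoon) whose
  peak-to-trough range is ~10 deg C in the open field and ~15 deg C under
  plastic, matching the wider thermal amplitude of a greenhouse;
* stationary AR(1) noise at the hourly step (white noise at hourly scale
  is unrealistically rough and makes threshold recovery artificially easy);
* deterministic year-to-year mean offsets (default −2…+2 deg C across
  years).  Between-season thermal contrast is what identifies the base
  temperature — cool and warm seasons must reach the same GDD total over
  different durations — so the offsets are part of the stated world, not
  noise.

Phenology is generated by the exact inverse of the harvest forecaster: a
virtual cultivar with known cardinal temperatures and stage-wise GDD
requirements develops through the simulated weather, so every estimator
can be scored against the truth that produced its data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .forecasting import NonConvergenceError
from .gdd import ThermalThresholds, hourly_contribution_array
from .phenology import MaturationSample, SeasonPhenology
from .weather_io import HourlyTemperatureSeries

__all__ = [
    "WeatherScenario",
    "VirtualCultivar",
    "generate_weather",
    "generate_phenology",
    "generate_maturation_series",
    "generate_dataset",
    "DEFAULT_INTERANNUAL_OFFSETS",
]

DEFAULT_INTERANNUAL_OFFSETS = (-2.0, -1.0, 0.0, 1.0, 2.0)

# default bud-break dates: mid-March outdoors; forced to late January under
# plastic, where covering plus cyanamide brings bud break to mid-winter.
BUD_BREAK_OPEN_FIELD = (3, 15)
BUD_BREAK_GREENHOUSE = (1, 20)


@dataclass(frozen=True)
class WeatherScenario:
    """Parameters of the simulated climate.

    ``annual_amplitude`` is the half-range of the annual cycle (8 deg C
    puts January means near 10.5 and August means near 26.5 deg C);
    ``diurnal_amplitude`` is the full day-night range.  ``noise_sd`` is the
    stationary standard deviation of the AR(1) hourly residual and
    ``ar_coefficient`` its lag-1 autocorrelation.  ``interannual_offsets``
    are added to the annual mean year by year (cycled when n_years exceeds
    the pattern length).
    """

    annual_mean: float = 18.5
    annual_amplitude: float = 8.0
    diurnal_amplitude: float = 10.0
    noise_sd: float = 1.5
    ar_coefficient: float = 0.9
    site: str = "open_field"
    n_years: int = 5
    seed: int = 0
    start_year: int = 2003
    interannual_offsets: tuple[float, ...] = DEFAULT_INTERANNUAL_OFFSETS

    def __post_init__(self) -> None:
        if self.annual_amplitude < 0 or self.diurnal_amplitude < 0:
            raise ValueError("amplitudes must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.ar_coefficient < 1:
            raise ValueError("ar_coefficient must lie in [0, 1)")
        if self.n_years < 1:
            raise ValueError("n_years must be >= 1")
        if self.site not in ("open_field", "greenhouse"):
            raise ValueError(f"unknown site {self.site!r}")

    @classmethod
    def open_field(cls, **kw) -> "WeatherScenario":
        return cls(site="open_field", diurnal_amplitude=10.0, **kw)

    @classmethod
    def greenhouse(cls, **kw) -> "WeatherScenario":
        """Wider diurnal range and a milder winter than the open field."""
        kw.setdefault("annual_mean", 20.0)
        return cls(site="greenhouse", diurnal_amplitude=15.0, **kw)

    def bud_break_for(self, year: int) -> date:
        month, day = (
            BUD_BREAK_GREENHOUSE if self.site == "greenhouse" else BUD_BREAK_OPEN_FIELD
        )
        return date(year, month, day)


@dataclass(frozen=True)
class VirtualCultivar:
    """Ground-truth thermal behaviour of a simulated cultivar.

    Defaults mirror the fitted table-grape values — base 5 deg C, upper
    threshold 30 deg C, 694 GDD bud break to bloom and 939 GDD bloom to
    harvest — so parameter-recovery tests double as checks against the
    published operating point.
    """

    t_base: float = 5.0
    t_upper: float = 30.0
    gdd_budbreak_to_bloom: float = 694.0
    gdd_bloom_to_harvest: float = 939.0

    def __post_init__(self) -> None:
        if not self.t_base < self.t_upper:
            raise ValueError("t_base must be below t_upper")
        if self.gdd_budbreak_to_bloom <= 0 or self.gdd_bloom_to_harvest <= 0:
            raise ValueError("stage GDD requirements must be positive")

    @property
    def thresholds(self) -> ThermalThresholds:
        return ThermalThresholds(t_base=self.t_base, t_upper=self.t_upper)

    @property
    def gdd_total(self) -> float:
        return self.gdd_budbreak_to_bloom + self.gdd_bloom_to_harvest


def _ar1(rng: np.random.Generator, n: int, sd: float, phi: float) -> np.ndarray:
    """Stationary AR(1) noise with marginal standard deviation ``sd``."""
    if sd == 0:
        return np.zeros(n)
    eps = rng.normal(0.0, sd * np.sqrt(1.0 - phi**2), size=n)
    out = np.empty(n)
    out[0] = rng.normal(0.0, sd)
    for t in range(1, n):
        out[t] = phi * out[t - 1] + eps[t]
    return out


def generate_weather(scenario: WeatherScenario) -> list[HourlyTemperatureSeries]:
    """One full calendar year of hourly temperatures per simulated season.

    Identical scenario (including seed) -> bit-identical output.
    """
    rng = np.random.default_rng(scenario.seed)
    out = []
    for k in range(scenario.n_years):
        year = scenario.start_year + k
        offset = scenario.interannual_offsets[k % len(scenario.interannual_offsets)] if scenario.interannual_offsets else 0.0
        idx = pd.date_range(f"{year}-01-01", f"{year}-12-31 23:00", freq="h")
        doy = idx.dayofyear.to_numpy(dtype=float)
        hour = idx.hour.to_numpy(dtype=float)
        annual = -scenario.annual_amplitude * np.cos(2 * np.pi * (doy - 15.0) / 365.25)
        diurnal = -(scenario.diurnal_amplitude / 2.0) * np.cos(2 * np.pi * (hour - 5.0) / 24.0)
        temps = (
            scenario.annual_mean
            + offset
            + annual
            + diurnal
            + _ar1(rng, len(idx), scenario.noise_sd, scenario.ar_coefficient)
        )
        out.append(
            HourlyTemperatureSeries(
                site_label=f"{scenario.site}-{year}", data=pd.Series(temps, index=idx)
            )
        )
    return out


def generate_phenology(
    weather: HourlyTemperatureSeries,
    cultivar: VirtualCultivar,
    bud_break: date,
    season: str | None = None,
    site: str = "open_field",
) -> SeasonPhenology:
    """Develop the virtual cultivar through one season's weather.

    Full bloom is the first date on which cumulative GDD from bud break
    (inclusive) reaches the bud-break→bloom requirement; harvest the first
    date reaching the sum of both stage requirements.  This is the exact
    inverse of the GDD harvest forecaster, so forecasting a generated
    season with its own realised requirement returns its harvest date.
    """
    last = weather.end.date()
    vals = weather.slice_dates(bud_break, last)
    n_days = len(vals) // 24
    if n_days < 1 or len(vals) % 24:
        vals = vals.iloc[: n_days * 24]
    if n_days < 1:
        raise NonConvergenceError(f"no complete days after {bud_break}")
    gdh = (
        hourly_contribution_array(vals.to_numpy(dtype=float), cultivar.thresholds)
        .reshape(n_days, 24)
        .sum(axis=1)
    )
    cum = np.cumsum(gdh / 24.0)
    k_bloom = int(np.searchsorted(cum, cultivar.gdd_budbreak_to_bloom))
    k_harvest = int(np.searchsorted(cum, cultivar.gdd_total))
    if k_harvest >= n_days:
        raise NonConvergenceError(
            f"requirement {cultivar.gdd_total:.0f} GDD not reached in the "
            f"{n_days} simulated days from {bud_break}"
        )
    return SeasonPhenology(
        season=season if season is not None else str(bud_break.year),
        site=site,  # type: ignore[arg-type]
        bud_break=bud_break,
        full_bloom=bud_break + timedelta(days=k_bloom),
        harvest=bud_break + timedelta(days=k_harvest),
    )


def generate_maturation_series(
    harvest: date,
    weeks_before: int,
    seed: int = 0,
    threshold: float = 18.0,
) -> list[MaturationSample]:
    """Weekly berry samples whose maturation index first exceeds the
    threshold exactly on the harvest-date sample.

    Soluble solids rise and acidity falls toward ripeness; the index is
    built first (monotone increasing, crossing on the last sample) and the
    acidity back-computed as tss/mi, mimicking how the index is measured.
    """
    if weeks_before < 1:
        raise ValueError("weeks_before must be >= 1")
    rng = np.random.default_rng(seed)
    mi = np.empty(weeks_before + 1)
    mi[-1] = threshold + rng.uniform(0.3, 1.2)  # first crossing, on harvest day
    mi[-2] = threshold - rng.uniform(0.2, 1.0)
    for k in range(weeks_before - 2, -1, -1):
        mi[k] = mi[k + 1] * rng.uniform(0.75, 0.92)
    tss = np.linspace(19.5 - 0.9 * weeks_before, 19.5, weeks_before + 1)
    tss = np.maximum(tss, 10.0)
    samples = []
    for k in range(weeks_before + 1):
        d = harvest - timedelta(weeks=weeks_before - k)
        samples.append(MaturationSample(date=d, tss=float(tss[k]), ta=float(tss[k] / mi[k])))
    return samples


def constant_season_dataset(
    temps_by_year: dict[int, float],
    cultivar: VirtualCultivar,
    days: int = 420,
) -> tuple[dict[str, HourlyTemperatureSeries], dict[str, SeasonPhenology]]:
    """Seasons at constant temperature — the sharpest estimator test bed.

    Each simulated year holds its temperature fixed, so a season's daily
    GDD is known in closed form and its duration follows exactly from the
    cultivar's requirement.  Choosing the total requirement just above a
    common day boundary makes the realised bud-break→harvest GDD *exactly*
    equal across seasons at the true cardinal temperatures (zero CV), which
    pins the estimators to the truth with no stochastic or discretisation
    floor.  Include seasons above the upper threshold when the cap itself
    must be identifiable.
    """
    weather_by_season: dict[str, HourlyTemperatureSeries] = {}
    phenology_by_season: dict[str, SeasonPhenology] = {}
    for year, temp in temps_by_year.items():
        idx = pd.date_range(f"{year}-01-01", periods=days * 24, freq="h")
        series = HourlyTemperatureSeries(
            site_label=f"const-{temp}C-{year}",
            data=pd.Series(float(temp), index=idx),
        )
        sid = str(year)
        weather_by_season[sid] = series
        phenology_by_season[sid] = generate_phenology(
            series, cultivar, date(year, 1, 1), season=sid
        )
    return weather_by_season, phenology_by_season


def generate_dataset(
    scenario: WeatherScenario, cultivar: VirtualCultivar
) -> tuple[dict[str, HourlyTemperatureSeries], dict[str, SeasonPhenology]]:
    """Weather and phenology for every simulated season, keyed by season id."""
    weather_by_season: dict[str, HourlyTemperatureSeries] = {}
    phenology_by_season: dict[str, SeasonPhenology] = {}
    for series in generate_weather(scenario):
        year = series.start.year
        sid = str(year)
        phen = generate_phenology(
            series,
            cultivar,
            scenario.bud_break_for(year),
            season=sid,
            site=scenario.site,
        )
        weather_by_season[sid] = series
        phenology_by_season[sid] = phen
    return weather_by_season, phenology_by_season
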