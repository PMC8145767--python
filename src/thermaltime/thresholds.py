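"""Cardinal-temperature estimation from multi-season phenology and weather.

The premise of thermal time is that a cultivar needs a fixed amount of heat
— not a fixed number of days — between two phenological stages.  At the
true base temperature T_b the growing degree-day total between bud break
and harvest is therefore (nearly) constant across seasons, however cool or
warm each season was.  Every estimator here exploits that stability:

``sd_gdd``
    pick the T_b minimising the between-season standard deviation of GDD;
``sd_days``
    the same SD expressed in day-equivalents, dividing by the grand mean
    of (seasonal mean temperature − T_b);
``cv_gdd``
    minimise the coefficient of variation (SD/mean) of GDD — scale-free,
    and the criterion usually preferred because the absolute SD shrinks
    mechanically as T_b rises;
``re``
    the regression-coefficient method: the T_b at which the least-squares
    slope of seasonal GDD on seasonal mean temperature crosses zero;
``x_intercept``
    regress developmental rate 1/d_i on seasonal mean temperature T̄_i and
    take the temperature at which the fitted rate is zero.

All grid criteria evaluate GDD with the hourly engine (uncapped while T_b
is being selected); the classical mean-temperature shortcut
GDD_i = d_i (T̄_i − T_b) is provided only as a cross-check oracle.  The
upper threshold T_u is selected afterwards by re-running the CV criterion
over a T_u grid with T_b held fixed, or jointly via the paired grid scan.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .gdd import ThermalThresholds, gdd_between_stages
from .phenology import SeasonPhenology
from .weather_io import HourlyTemperatureSeries

__all__ = [
    "InsufficientDataError",
    "NoSolutionError",
    "SeasonThermalSummary",
    "ThresholdEstimate",
    "CvScanCurve",
    "summarize_seasons",
    "criterion_sd_gdd",
    "criterion_cv_gdd",
    "criterion_sd_days",
    "estimate_tb",
    "five_method_table",
    "scan_cv",
    "paired_scan",
    "subset_stability",
    "mean_temperature_gdd",
    "METHODS",
]

METHODS = ("sd_gdd", "sd_days", "cv_gdd", "re", "x_intercept")

DEFAULT_TB_GRID = (-5.0, 20.0, 0.01)  # start, stop, step — Table-1 style estimates
DEFAULT_TB_SCAN = (3.0, 12.0, 1.0)  # Fig.-1 style CV scan over candidate T_b
DEFAULT_TU_SCAN = (25.0, 45.0, 1.0)  # Fig.-1 style CV scan over candidate T_u

_GRID_CHUNK = 256  # rows of the (grid x hours) broadcast evaluated at once


class InsufficientDataError(ValueError):
    """Fewer seasons than the estimator needs."""


class NoSolutionError(ValueError):
    """The criterion has no admissible optimum / root in the searched range."""


@dataclass(frozen=True)
class SeasonThermalSummary:
    """Duration d_i, mean temperature T̄_i and GDD_i of one season's interval."""

    season: str
    d: int
    t_mean: float
    gdd: float

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ValueError(f"season {self.season}: duration {self.d} < 1")
        if self.gdd < 0:
            raise ValueError(f"season {self.season}: negative gdd {self.gdd}")


@dataclass(frozen=True)
class ThresholdEstimate:
    """An estimated cardinal temperature (pair) with its criterion value."""

    method: str
    t_base: float
    criterion_value: float
    t_upper: float | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.criterion_value):
            raise ValueError(f"{self.method}: non-finite criterion value")


@dataclass(frozen=True)
class CvScanCurve:
    """CV(%) of between-season GDD along one cardinal-temperature axis."""

    axis: Literal["t_base", "t_upper"]
    points: pd.DataFrame  # columns: temperature, cv_percent

    def __post_init__(self) -> None:
        t = self.points["temperature"].to_numpy()
        if len(t) < 2 or not np.all(np.diff(t) > 0):
            raise ValueError("scan needs >= 2 strictly increasing temperatures")

    @property
    def minimum(self) -> tuple[float, float]:
        """(temperature, cv) at the scan minimum; ties -> lowest temperature."""
        k = int(self.points["cv_percent"].idxmin())
        row = self.points.loc[k]
        return float(row["temperature"]), float(row["cv_percent"])

    def to_csv(self, path) -> None:
        self.points.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# season summaries and scalar criteria
# ---------------------------------------------------------------------------


def _interval_hours(
    weather: HourlyTemperatureSeries,
    phen: SeasonPhenology,
    from_stage: str,
    to_stage: str,
) -> np.ndarray:
    """Hourly temperatures over the stage interval (end date excluded)."""
    from datetime import timedelta

    from .gdd import MissingDataError

    from_date = phen.stage_date(from_stage)
    to_date = phen.stage_date(to_stage)
    vals = weather.slice_dates(from_date, to_date - timedelta(days=1))
    n_days = (to_date - from_date).days
    if len(vals) != 24 * n_days:
        raise MissingDataError(
            f"season {phen.season}: weather covers {len(vals)} of {24 * n_days} hours "
            f"in {from_date}..{to_date}"
        )
    return vals.to_numpy(dtype=float)


def summarize_seasons(
    weather_by_season: Mapping[str, HourlyTemperatureSeries],
    phenology_by_season: Mapping[str, SeasonPhenology],
    thresholds: ThermalThresholds,
    from_stage: str = "bud_break",
    to_stage: str = "harvest",
) -> list[SeasonThermalSummary]:
    """One (d_i, T̄_i, GDD_i) summary per season at the given thresholds."""
    seasons = sorted(phenology_by_season)
    if len(seasons) < 2:
        raise InsufficientDataError(f"need >= 2 seasons, got {len(seasons)}")
    out = []
    for sid in seasons:
        phen = phenology_by_season[sid]
        gdd, days = gdd_between_stages(
            weather_by_season[sid], phen, from_stage, to_stage, thresholds
        )
        hours = _interval_hours(weather_by_season[sid], phen, from_stage, to_stage)
        out.append(
            SeasonThermalSummary(season=sid, d=days, t_mean=float(hours.mean()), gdd=gdd)
        )
    return out


def criterion_sd_gdd(summaries: Sequence[SeasonThermalSummary]) -> float:
    """Between-season sample SD (n−1 denominator) of GDD, in degree-days."""
    if len(summaries) < 2:
        raise InsufficientDataError("need >= 2 seasons for an SD")
    return float(np.std([s.gdd for s in summaries], ddof=1))


def criterion_cv_gdd(summaries: Sequence[SeasonThermalSummary]) -> float:
    """Between-season coefficient of variation of GDD, in percent."""
    gdd = np.array([s.gdd for s in summaries], dtype=float)
    mean = gdd.mean()
    if mean <= 0:
        raise NoSolutionError("mean GDD not positive; CV undefined")
    return float(100.0 * np.std(gdd, ddof=1) / mean)


def criterion_sd_days(summaries: Sequence[SeasonThermalSummary], t_base: float) -> float:
    """SD of GDD converted to day-equivalents.

    Divides the GDD standard deviation by the grand mean across seasons of
    (T̄_i − t_base), i.e. by the average degree-days a day contributes; a
    non-positive divisor means t_base sits at or above the seasonal mean
    temperatures and the transform is degenerate.
    """
    divisor = float(np.mean([s.t_mean for s in summaries])) - t_base
    if divisor <= 0:
        raise NoSolutionError(
            f"grand mean (T̄ − t_base) = {divisor:.3f} not positive at t_base={t_base}"
        )
    return criterion_sd_gdd(summaries) / divisor


def mean_temperature_gdd(d: int, t_mean: float, t_base: float) -> float:
    """Classical daily-mean shortcut GDD = d (T̄ − T_b), as a cross-check oracle.

    Agrees with the hourly engine on constant-temperature series (uncapped,
    all hours above T_b); used only to validate the hourly path in tests.
    """
    return d * max(t_mean - t_base, 0.0)


# ---------------------------------------------------------------------------
# vectorised GDD grids
# ---------------------------------------------------------------------------


def _gdd_totals_grid(
    hours_by_season: Sequence[np.ndarray],
    tb_grid: np.ndarray,
    t_upper: float | None,
) -> np.ndarray:
    """GDD totals, shape (len(tb_grid), n_seasons), at each candidate T_b.

    The cap T_u − T_b moves with T_b when ``t_upper`` is fixed, matching
    the hourly engine exactly; evaluation is chunked over the grid to bound
    the broadcast size.
    """
    tb_grid = np.asarray(tb_grid, dtype=float)
    out = np.empty((tb_grid.size, len(hours_by_season)))
    for j, hours in enumerate(hours_by_season):
        for k0 in range(0, tb_grid.size, _GRID_CHUNK):
            tb = tb_grid[k0 : k0 + _GRID_CHUNK, None]
            excess = np.maximum(hours[None, :] - tb, 0.0)
            if t_upper is not None:
                np.minimum(excess, t_upper - tb, out=excess)
            out[k0 : k0 + tb.shape[0], j] = excess.sum(axis=1) / 24.0
    return out


def _cv_percent_rows(gdd: np.ndarray) -> np.ndarray:
    """CV% per grid row; rows with non-positive mean GDD get +inf."""
    mean = gdd.mean(axis=1)
    sd = gdd.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, 100.0 * sd / mean, np.inf)
    return cv


def _grid(rng: tuple[float, float, float]) -> np.ndarray:
    start, stop, step = rng
    if step <= 0 or stop < start:
        raise ValueError(f"bad grid specification {rng}")
    n = int(round((stop - start) / step))
    return start + step * np.arange(n + 1)


def _collect_hours(
    weather_by_season: Mapping[str, HourlyTemperatureSeries],
    phenology_by_season: Mapping[str, SeasonPhenology],
    from_stage: str,
    to_stage: str,
) -> tuple[list[str], list[np.ndarray]]:
    seasons = sorted(phenology_by_season)
    if len(seasons) < 2:
        raise InsufficientDataError(f"need >= 2 seasons, got {len(seasons)}")
    hours = [
        _interval_hours(weather_by_season[s], phenology_by_season[s], from_stage, to_stage)
        for s in seasons
    ]
    return seasons, hours


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------


def _regression_slope(t_mean: np.ndarray, gdd_rows: np.ndarray) -> np.ndarray:
    """Least-squares slope of GDD_i on T̄_i, one value per grid row."""
    tc = t_mean - t_mean.mean()
    denom = float((tc**2).sum())
    if denom == 0:
        raise NoSolutionError("no between-season spread in mean temperature")
    return (gdd_rows - gdd_rows.mean(axis=1, keepdims=True)) @ tc / denom


def estimate_tb(
    method: str,
    weather_by_season: Mapping[str, HourlyTemperatureSeries],
    phenology_by_season: Mapping[str, SeasonPhenology],
    search: tuple[float, float, float] = DEFAULT_TB_GRID,
    from_stage: str = "bud_break",
    to_stage: str = "harvest",
) -> ThresholdEstimate:
    """Estimate the base temperature by one of the five stability criteria.

    Grid criteria (``sd_gdd``, ``sd_days``, ``cv_gdd``) return the grid
    argmin over ``search`` = (start, stop, step); ``re`` brackets the zero
    of the GDD-on-T̄ slope on the grid and refines it with Brent's method;
    ``x_intercept`` is grid-free.  GDD runs uncapped (T_u selection comes
    later).
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    seasons, hours = _collect_hours(
        weather_by_season, phenology_by_season, from_stage, to_stage
    )
    durations = np.array(
        [
            (
                phenology_by_season[s].stage_date(to_stage)
                - phenology_by_season[s].stage_date(from_stage)
            ).days
            for s in seasons
        ],
        dtype=float,
    )
    t_mean = np.array([h.mean() for h in hours])

    if method == "x_intercept":
        res = stats.linregress(t_mean, 1.0 / durations)
        if res.slope <= 0:
            raise NoSolutionError(
                f"developmental-rate regression slope {res.slope:.3g} not positive"
            )
        return ThresholdEstimate(
            method=method,
            t_base=float(-res.intercept / res.slope),
            criterion_value=float(res.intercept),
        )

    grid = _grid(search)
    gdd = _gdd_totals_grid(hours, grid, t_upper=None)

    if method == "re":
        slopes = _regression_slope(t_mean, gdd)
        signs = np.sign(slopes)
        change = np.nonzero(np.diff(signs) != 0)[0]
        if change.size == 0:
            raise NoSolutionError(
                f"regression slope has no sign change in [{grid[0]}, {grid[-1]}]"
            )
        k = int(change[0])

        def slope_at(tb: float) -> float:
            g = _gdd_totals_grid(hours, np.array([tb]), t_upper=None)
            return float(_regression_slope(t_mean, g)[0])

        root = float(optimize.brentq(slope_at, grid[k], grid[k + 1], xtol=1e-10))
        return ThresholdEstimate(method=method, t_base=root, criterion_value=slope_at(root))

    if method == "sd_gdd":
        crit = gdd.std(axis=1, ddof=1)
    elif method == "cv_gdd":
        crit = _cv_percent_rows(gdd)
    else:  # sd_days
        divisor = t_mean.mean() - grid
        with np.errstate(divide="ignore", invalid="ignore"):
            crit = np.where(divisor > 0, gdd.std(axis=1, ddof=1) / divisor, np.inf)
    if not np.isfinite(crit).any():
        raise NoSolutionError(f"{method}: criterion undefined over the whole grid")
    k = int(np.argmin(crit))
    return ThresholdEstimate(method=method, t_base=float(grid[k]), criterion_value=float(crit[k]))


def five_method_table(
    weather_by_season: Mapping[str, HourlyTemperatureSeries],
    phenology_by_season: Mapping[str, SeasonPhenology],
    search: tuple[float, float, float] = DEFAULT_TB_GRID,
    from_stage: str = "bud_break",
    to_stage: str = "harvest",
) -> pd.DataFrame:
    """Run all five T_b estimators; non-convergent methods get NaN rows."""
    rows = []
    for method in METHODS:
        try:
            est = estimate_tb(
                method, weather_by_season, phenology_by_season, search, from_stage, to_stage
            )
            rows.append(
                {
                    "method": method,
                    "t_base": est.t_base,
                    "criterion": est.criterion_value,
                    "note": "",
                }
            )
        except NoSolutionError as exc:
            rows.append(
                {"method": method, "t_base": np.nan, "criterion": np.nan, "note": str(exc)}
            )
    return pd.DataFrame(rows)


def scan_cv(
    weather_by_season: Mapping[str, HourlyTemperatureSeries],
    phenology_by_season: Mapping[str, SeasonPhenology],
    axis: Literal["t_base", "t_upper"],
    fixed_other: float | None = None,
    scan_range: tuple[float, float, float] | None = None,
    from_stage: str = "bud_break",
    to_stage: str = "harvest",
) -> CvScanCurve:
    """CV(%) of between-season GDD along a T_b or T_u grid.

    For ``axis="t_base"`` the other threshold defaults to uncapped; for
    ``axis="t_upper"`` a fixed T_b must be supplied (T_u is selected after
    T_b, with T_b held at its chosen value).
    """
    _, hours = _collect_hours(weather_by_season, phenology_by_season, from_stage, to_stage)
    if axis == "t_base":
        grid = _grid(scan_range if scan_range is not None else DEFAULT_TB_SCAN)
        gdd = _gdd_totals_grid(hours, grid, t_upper=fixed_other)
        if fixed_other is not None and np.any(grid >= fixed_other):
            raise ValueError("t_base grid reaches the fixed t_upper")
    elif axis == "t_upper":
        if fixed_other is None:
            raise ValueError("t_upper scan requires a fixed t_base")
        grid = _grid(scan_range if scan_range is not None else DEFAULT_TU_SCAN)
        if np.any(grid <= fixed_other):
            raise ValueError("t_upper grid reaches the fixed t_base")
        gdd = np.empty((grid.size, len(hours)))
        for j, h in enumerate(hours):
            excess = np.maximum(h[None, :] - fixed_other, 0.0)
            gdd[:, j] = (
                np.minimum(excess, (grid - fixed_other)[:, None]).sum(axis=1) / 24.0
            )
    else:
        raise ValueError(f"axis must be 't_base' or 't_upper', got {axis!r}")
    cv = _cv_percent_rows(gdd)
    return CvScanCurve(
        axis=axis, points=pd.DataFrame({"temperature": grid, "cv_percent": cv})
    )


def paired_scan(
    weather_by_season: Mapping[str, HourlyTemperatureSeries],
    phenology_by_season: Mapping[str, SeasonPhenology],
    tb_range: tuple[float, float, float] = DEFAULT_TB_SCAN,
    tu_range: tuple[float, float, float] = DEFAULT_TU_SCAN,
    from_stage: str = "bud_break",
    to_stage: str = "harvest",
) -> ThresholdEstimate:
    """Joint (T_b, T_u) grid search minimising the CV of between-season GDD.

    Ties are broken toward the smallest T_b, then the smallest T_u.
    """
    _, hours = _collect_hours(weather_by_season, phenology_by_season, from_stage, to_stage)
    tb_grid = _grid(tb_range)
    tu_grid = _grid(tu_range)
    best: tuple[float, float, float] | None = None  # (cv, tb, tu)
    for tu in tu_grid:
        admissible = tb_grid[tb_grid < tu]
        if admissible.size == 0:
            continue
        gdd = _gdd_totals_grid(hours, admissible, t_upper=float(tu))
        cv = _cv_percent_rows(gdd)
        k = int(np.argmin(cv))
        cand = (float(cv[k]), float(admissible[k]), float(tu))
        if best is None or cand[0] < best[0] - 1e-12:
            best = cand
        # equal CV: keep earlier (smaller tb, then smaller tu) — scan order
        # already visits tu ascending, and argmin picks the smallest tb.
        elif abs(cand[0] - best[0]) <= 1e-12 and (cand[1], cand[2]) < (best[1], best[2]):
            best = cand
    if best is None:
        raise NoSolutionError("no (t_base < t_upper) pair in the searched ranges")
    return ThresholdEstimate(
        method="paired_scan", t_base=best[1], t_upper=best[2], criterion_value=best[0]
    )


def subset_stability(
    method: str,
    weather_by_season: Mapping[str, HourlyTemperatureSeries],
    phenology_by_season: Mapping[str, SeasonPhenology],
    leave_out: Sequence[set[str] | frozenset[str]] = (),
    search: tuple[float, float, float] = DEFAULT_TB_GRID,
    from_stage: str = "bud_break",
    to_stage: str = "harvest",
) -> pd.DataFrame:
    """Re-estimate T_b on season subsets to probe the criterion's stability.

    ``leave_out`` lists sets of season ids to exclude; the full-set
    estimate is always included first (an empty list yields only it).
    Subsets where the estimator fails are reported with NaN and the reason,
    not dropped.
    """
    subsets: list[frozenset[str]] = [frozenset()] + [frozenset(s) for s in leave_out]
    rows = []
    for excluded in subsets:
        kept = {s: p for s, p in phenology_by_season.items() if s not in excluded}
        label = "none" if not excluded else ",".join(sorted(excluded))
        if len(kept) < 2:
            raise InsufficientDataError(
                f"subset excluding {{{label}}} keeps {len(kept)} season(s); need >= 2"
            )
        try:
            est = estimate_tb(method, weather_by_season, kept, search, from_stage, to_stage)
            rows.append(
                {
                    "method": method,
                    "excluded": label,
                    "t_base": est.t_base,
                    "criterion": est.criterion_value,
                    "note": "",
                }
            )
        except NoSolutionError as exc:
            rows.append(
                {
                    "method": method,
                    "excluded": label,
                    "t_base": np.nan,
                    "criterion": np.nan,
                    "note": str(exc),
                }
            )
    return pd.DataFrame(rows)
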