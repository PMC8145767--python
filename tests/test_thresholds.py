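from datetime import date, timedelta

import numpy as np
import pytest

from thermaltime import tables
from thermaltime.gdd import ThermalThresholds
from thermaltime.phenology import SeasonPhenology
from thermaltime.synthetic import VirtualCultivar, WeatherScenario, constant_season_dataset, generate_dataset
from thermaltime.thresholds import (
    InsufficientDataError,
    NoSolutionError,
    SeasonThermalSummary,
    criterion_cv_gdd,
    criterion_sd_days,
    criterion_sd_gdd,
    estimate_tb,
    five_method_table,
    paired_scan,
    scan_cv,
    subset_stability,
    summarize_seasons,
    mean_temperature_gdd,
)

from .conftest import constant_series

TABLE2_OPEN_FIELD_TOTALS = [1652.0, 1490.0, 1740.0, 1634.0, 1650.0]


def _summaries(gdds, t_mean=20.0, d=100):
    return [
        SeasonThermalSummary(season=str(k), d=d, t_mean=t_mean, gdd=g)
        for k, g in enumerate(gdds)
    ]


def _const_dataset(spec):
    """spec: {season: (temp, duration_days)} with manually chosen durations."""
    weather, phen = {}, {}
    for k, (sid, (temp, dur)) in enumerate(spec.items()):
        start = date(2001 + k, 3, 1)
        weather[sid] = constant_series(
            temp, dur + 10, start=start.isoformat(), site_label=sid
        )
        phen[sid] = SeasonPhenology(
            season=sid, site="open_field", bud_break=start,
            harvest=start + timedelta(days=dur),
        )
    return weather, phen


class TestSummaries:
    def test_constant_season_summary(self):
        weather, phen = _const_dataset({"a": (20.0, 100), "b": (20.0, 100)})
        summ = summarize_seasons(weather, phen, ThermalThresholds(5.0))
        assert all(s.d == 100 and s.t_mean == 20.0 for s in summ)
        assert all(s.gdd == pytest.approx(1500.0) for s in summ)
        # identical seasons give identical summaries
        assert summ[0].gdd == summ[1].gdd

    def test_fewer_than_two_seasons_rejected(self):
        weather, phen = _const_dataset({"a": (20.0, 100)})
        with pytest.raises(InsufficientDataError):
            summarize_seasons(weather, phen, ThermalThresholds(5.0))

    def test_published_totals_accepted_as_summaries(self):
        summ = tables.heat_requirement_summaries("open_field")
        assert [s.gdd for s in summ] == TABLE2_OPEN_FIELD_TOTALS

    def test_mean_temperature_shortcut_matches_engine_on_constant_days(self):
        weather, phen = _const_dataset({"a": (20.0, 100), "b": (14.0, 150)})
        for s in summarize_seasons(weather, phen, ThermalThresholds(5.0)):
            assert s.gdd == pytest.approx(mean_temperature_gdd(s.d, s.t_mean, 5.0))


class TestScalarCriteria:
    def test_sd_gdd_of_published_totals(self):
        # sample SD (n-1) of the five open-field totals
        assert criterion_sd_gdd(_summaries(TABLE2_OPEN_FIELD_TOTALS)) == pytest.approx(
            90.21, abs=0.005
        )

    def test_sd_gdd_degenerate_and_closed_form(self):
        assert criterion_sd_gdd(_summaries([1000.0] * 4)) == 0.0
        assert criterion_sd_gdd(_summaries([10.0, 12.0])) == pytest.approx(np.sqrt(2))

    def test_cv_gdd_of_published_totals(self):
        assert criterion_cv_gdd(_summaries(TABLE2_OPEN_FIELD_TOTALS)) == pytest.approx(
            5.52, abs=0.005
        )

    def test_cv_gdd_guards(self):
        assert criterion_cv_gdd(_summaries([1000.0] * 3)) == 0.0
        with pytest.raises(NoSolutionError):
            criterion_cv_gdd(_summaries([0.0, 0.0]))

    def test_sd_days_transform(self):
        summ = _summaries(TABLE2_OPEN_FIELD_TOTALS, t_mean=19.0)
        # divisor = grand mean (T̄ − T_b) = 14
        assert criterion_sd_days(summ, t_base=5.0) == pytest.approx(90.21 / 14, abs=0.001)
        assert criterion_sd_days(_summaries([1000.0] * 3), 5.0) == 0.0
        with pytest.raises(NoSolutionError):
            criterion_sd_days(summ, t_base=19.0)

    def test_criteria_invariant_to_season_order(self):
        summ = _summaries(TABLE2_OPEN_FIELD_TOTALS)
        shuffled = list(reversed(summ))
        assert criterion_sd_gdd(summ) == criterion_sd_gdd(shuffled)
        assert criterion_cv_gdd(summ) == criterion_cv_gdd(shuffled)

    def test_cv_is_scale_free(self):
        summ = _summaries(TABLE2_OPEN_FIELD_TOTALS)
        scaled = _summaries([g * 3.7 for g in TABLE2_OPEN_FIELD_TOTALS])
        assert criterion_cv_gdd(summ) == pytest.approx(criterion_cv_gdd(scaled))


class TestEstimateTb:
    def test_x_intercept_analytic(self):
        # noiseless linear rate: 1/d = (T̄ − 5)/1000 through (15, 1/100), (25, 1/50)
        weather, phen = _const_dataset({"cool": (15.0, 100), "warm": (25.0, 50)})
        est = estimate_tb("x_intercept", weather, phen)
        assert est.t_base == pytest.approx(5.0, abs=1e-9)

    def test_x_intercept_negative_slope_rejected(self):
        weather, phen = _const_dataset({"cool": (15.0, 50), "warm": (25.0, 100)})
        with pytest.raises(NoSolutionError):
            estimate_tb("x_intercept", weather, phen)

    def test_cv_argmin_on_zero_cv_construction(self):
        # durations chosen so GDD at T_b=6 is 1000 in both seasons → CV = 0 at 6
        weather, phen = _const_dataset({"cool": (16.0, 100), "warm": (26.0, 50)})
        est = estimate_tb("cv_gdd", weather, phen, search=(0.0, 12.0, 0.01))
        assert est.t_base == pytest.approx(6.0, abs=0.01)
        assert est.criterion_value == pytest.approx(0.0, abs=1e-9)

    def test_re_root_has_negligible_slope(self):
        weather, phen = _const_dataset(
            {"a": (16.0, 100), "b": (21.0, 1000 // 15), "c": (26.0, 50)}
        )
        est = estimate_tb("re", weather, phen, search=(0.0, 12.0, 0.01))
        assert est.t_base == pytest.approx(6.0, abs=0.2)
        # refitted slope at the root is tiny relative to a grid neighbour's
        from thermaltime.thresholds import _collect_hours, _gdd_totals_grid, _regression_slope

        _, hours = _collect_hours(weather, phen, "bud_break", "harvest")
        t_mean = np.array([h.mean() for h in hours])
        grid = np.array([est.t_base, est.t_base + 0.01])
        slopes = _regression_slope(t_mean, _gdd_totals_grid(hours, grid, None))
        assert abs(slopes[0]) < 1e-6 * abs(slopes[1])

    def test_re_no_sign_change_raises(self):
        weather, phen = _const_dataset({"a": (16.0, 100), "b": (26.0, 100)})
        with pytest.raises(NoSolutionError):
            estimate_tb("re", weather, phen, search=(0.0, 5.0, 0.5))

    def test_unknown_method_rejected(self, noiseless_dataset):
        weather, phen = noiseless_dataset
        with pytest.raises(ValueError, match="unknown method"):
            estimate_tb("winkler", weather, phen)

    def test_five_methods_recover_noiseless_truth(self, noiseless_dataset):
        weather, phen = noiseless_dataset
        table = five_method_table(weather, phen, search=(-5.0, 20.0, 0.05))
        assert list(table["method"]) == list(
            ("sd_gdd", "sd_days", "cv_gdd", "re", "x_intercept")
        )
        assert (table["t_base"] - 5.0).abs().max() < 0.5


class TestScans:
    def test_tb_scan_minimum_on_zero_cv_construction(self):
        weather, phen = _const_dataset({"cool": (16.0, 100), "warm": (26.0, 50)})
        curve = scan_cv(weather, phen, axis="t_base", scan_range=(3.0, 12.0, 1.0))
        t, cv = curve.minimum
        assert (t, cv) == (6.0, pytest.approx(0.0, abs=1e-9))

    def test_tu_scan_flat_when_cap_never_binds(self):
        weather, phen = _const_dataset({"cool": (16.0, 100), "warm": (26.0, 50)})
        curve = scan_cv(
            weather, phen, axis="t_upper", fixed_other=6.0, scan_range=(27.0, 45.0, 1.0)
        )
        assert curve.points["cv_percent"].nunique() == 1

    def test_tu_scan_rises_for_small_tu_matches_brute_force(self):
        from .test_gdd import brute_force_total

        cult = VirtualCultivar(t_base=7.0, t_upper=31.0,
                               gdd_budbreak_to_bloom=660.0, gdd_bloom_to_harvest=901.0)
        weather, phen = constant_season_dataset(
            {2001: 15.0, 2002: 20.0, 2003: 27.0, 2004: 33.0, 2005: 35.0}, cult
        )
        curve = scan_cv(
            weather, phen, axis="t_upper", fixed_other=7.0, scan_range=(25.0, 45.0, 1.0)
        )
        cv = curve.points.set_index("temperature")["cv_percent"]
        assert cv[25.0] > cv[28.0] > cv[31.0]
        # brute-force recomputation at 3 grid points
        for tu in (25.0, 31.0, 40.0):
            totals = []
            for sid, p in phen.items():
                hours = weather[sid].slice_dates(
                    p.bud_break, p.harvest - timedelta(days=1)
                ).to_numpy()
                totals.append(brute_force_total(hours, 7.0, tu))
            expected = 100.0 * np.std(totals, ddof=1) / np.mean(totals)
            assert cv[tu] == pytest.approx(expected, abs=1e-9)

    def test_tu_scan_requires_fixed_tb(self, noiseless_dataset):
        weather, phen = noiseless_dataset
        with pytest.raises(ValueError, match="fixed t_base"):
            scan_cv(weather, phen, axis="t_upper")


class TestPairedScan:
    def test_single_pair_grid_returns_it(self):
        weather, phen = _const_dataset({"cool": (16.0, 100), "warm": (26.0, 50)})
        est = paired_scan(weather, phen, tb_range=(6.0, 6.0, 1.0), tu_range=(30.0, 30.0, 1.0))
        assert (est.t_base, est.t_upper) == (6.0, 30.0)

    def test_recovers_constructing_pair_exactly(self):
        cult = VirtualCultivar(t_base=7.0, t_upper=31.0,
                               gdd_budbreak_to_bloom=660.0, gdd_bloom_to_harvest=901.0)
        weather, phen = constant_season_dataset(
            {2001: 15.0, 2002: 20.0, 2003: 27.0, 2004: 33.0, 2005: 35.0}, cult
        )
        est = paired_scan(weather, phen, tb_range=(3.0, 12.0, 1.0), tu_range=(25.0, 45.0, 1.0))
        assert (est.t_base, est.t_upper) == (7.0, 31.0)
        assert est.criterion_value == pytest.approx(0.0, abs=1e-12)


class TestSubsetStability:
    def test_identical_seasons_identical_estimates(self):
        weather, phen = _const_dataset(
            {k: (20.0, 100) for k in ("a", "b", "c", "d")}
        )
        table = subset_stability(
            "cv_gdd", weather, phen, leave_out=[{"a"}, {"b"}], search=(0.0, 12.0, 0.5)
        )
        assert table["t_base"].nunique() == 1
        assert list(table["excluded"]) == ["none", "a", "b"]

    def test_empty_leave_out_single_estimate(self, noiseless_dataset):
        weather, phen = noiseless_dataset
        table = subset_stability("cv_gdd", weather, phen, search=(0.0, 12.0, 0.1))
        assert len(table) == 1 and table.loc[0, "excluded"] == "none"

    def test_noiseless_subsets_stay_near_truth(self, noiseless_dataset):
        weather, phen = noiseless_dataset
        seasons = sorted(phen)
        table = subset_stability(
            "cv_gdd", weather, phen,
            leave_out=[{seasons[0]}, {seasons[-1]}],
            search=(0.0, 12.0, 0.05),
        )
        assert (table["t_base"] - 5.0).abs().max() < 0.5

    def test_subset_too_small_rejected(self):
        weather, phen = _const_dataset({"a": (20.0, 100), "b": (20.0, 100)})
        with pytest.raises(InsufficientDataError):
            subset_stability("cv_gdd", weather, phen, leave_out=[{"a"}])


class TestNoiseDegradation:
    def test_recovery_error_grows_with_noise_on_average(self):
        """Mean |T_b error| over 20 seeds is monotone in the noise SD."""
        mean_err = []
        for noise in (0.3, 1.0, 2.5):
            errs = []
            for seed in range(20):
                weather, phen = generate_dataset(
                    WeatherScenario(noise_sd=noise, seed=seed), VirtualCultivar()
                )
                est = estimate_tb("cv_gdd", weather, phen, search=(-5.0, 20.0, 0.1))
                errs.append(abs(est.t_base - 5.0))
            mean_err.append(np.mean(errs))
        assert mean_err[0] < mean_err[1] < mean_err[2]
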