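from datetime import date, timedelta

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermaltime.gdd import (
    MissingDataError,
    ThermalThresholds,
    accumulate,
    daily_gdd,
    gdd_between_stages,
    hourly_contribution,
)
from thermaltime.phenology import SeasonPhenology

from .conftest import constant_series, make_series


def brute_force_total(temps, t_base, t_upper) -> float:
    """Independent oracle: plain Python loop over every hour, Eqs. as written."""
    total = 0.0
    day_sum = 0.0
    for h, t in enumerate(temps, start=1):
        if t <= t_base:
            contrib = 0.0
        elif t_upper is not None and t > t_upper:
            contrib = t_upper - t_base
        else:
            contrib = t - t_base
        day_sum += contrib
        if h % 24 == 0:
            total += day_sum / 24.0
            day_sum = 0.0
    return total


class TestHourlyContribution:
    @pytest.mark.parametrize(
        "t_h,expected",
        [(4.0, 0.0), (5.0, 0.0), (20.0, 15.0), (30.0, 25.0), (35.0, 25.0)],
    )
    def test_capped_branches(self, t_h, expected, thresholds_5_30):
        assert hourly_contribution(t_h, thresholds_5_30) == expected

    def test_uncapped_never_saturates(self):
        thr = ThermalThresholds(t_base=5.0)
        assert hourly_contribution(45.0, thr) == 40.0

    def test_degenerate_thresholds_rejected(self):
        with pytest.raises(ValueError):
            ThermalThresholds(t_base=5.0, t_upper=5.0)

    @given(t_h=st.floats(-40, 70), t_base=st.floats(-5, 20))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_contribution_bounded_by_cap(self, t_h, t_base):
        thr = ThermalThresholds(t_base=t_base, t_upper=t_base + 25.0)
        c = hourly_contribution(t_h, thr)
        assert 0.0 <= c <= 25.0 + 1e-9  # cap width up to float rounding


class TestDailyGdd:
    def test_constant_day(self, thresholds_5_30):
        s = constant_series(17.0, 1)
        assert daily_gdd(s, date(2005, 3, 1), thresholds_5_30) == pytest.approx(12.0)

    def test_split_day(self, thresholds_5_30):
        s = make_series([4.0] * 12 + [20.0] * 12)
        assert daily_gdd(s, date(2005, 3, 1), thresholds_5_30) == pytest.approx(7.5)

    def test_fully_capped_day(self, thresholds_5_30):
        s = constant_series(35.0, 1)
        assert daily_gdd(s, date(2005, 3, 1), thresholds_5_30) == pytest.approx(25.0)

    def test_incomplete_day_raises(self, thresholds_5_30):
        s = make_series(np.full(30, 20.0))
        with pytest.raises(MissingDataError, match="2005-03-02"):
            daily_gdd(s, date(2005, 3, 2), thresholds_5_30)


class TestAccumulate:
    def test_hundred_constant_days(self):
        s = constant_series(20.0, 100)
        acc = accumulate(s, date(2005, 3, 1), date(2005, 6, 8), ThermalThresholds(5.0))
        assert acc.n_days == 100
        assert acc.total == pytest.approx(1500.0)

    def test_single_day(self, thresholds_5_30):
        s = constant_series(17.0, 2)
        acc = accumulate(s, date(2005, 3, 1), date(2005, 3, 1), thresholds_5_30)
        assert acc.total == pytest.approx(12.0)

    def test_cumulative_is_running_sum_and_capped(self, thresholds_5_30):
        rng = np.random.default_rng(1)
        s = make_series(rng.uniform(-5, 45, 10 * 24))
        acc = accumulate(s, date(2005, 3, 1), date(2005, 3, 10), thresholds_5_30)
        np.testing.assert_allclose(
            acc.daily["cumulative"], np.cumsum(acc.daily["gdd"])
        )
        assert (acc.daily["gdd"] >= 0).all()
        assert (acc.daily["gdd"] <= 25.0 + 1e-12).all()

    def test_coverage_hole_raises(self, thresholds_5_30):
        s = constant_series(20.0, 3)
        with pytest.raises(MissingDataError):
            accumulate(s, date(2005, 3, 1), date(2005, 3, 5), thresholds_5_30)

    def test_csv_export(self, tmp_path, thresholds_5_30):
        s = constant_series(17.0, 3)
        acc = accumulate(s, date(2005, 3, 1), date(2005, 3, 3), thresholds_5_30)
        p = tmp_path / "acc.csv"
        acc.to_csv(p)
        header = p.read_text().splitlines()[0]
        assert header == "date,gdh,gdd,cumulative"


class TestStageIntervals:
    def _phen(self, bud_break, full_bloom=None, harvest=None):
        return SeasonPhenology(
            season="s", site="open_field",
            bud_break=bud_break, full_bloom=full_bloom, harvest=harvest,
        )

    def test_constant_19_degrees_116_days(self, thresholds_5_30):
        s = constant_series(19.0, 120, start="2020-03-01")
        phen = self._phen(date(2020, 3, 1), harvest=date(2020, 6, 25))
        gdd, days = gdd_between_stages(s, phen, "bud_break", "harvest", thresholds_5_30)
        assert days == 116
        assert gdd == pytest.approx(1624.0)

    def test_one_day_interval(self, thresholds_5_30):
        s = constant_series(17.0, 3, start="2020-03-01")
        phen = self._phen(date(2020, 3, 1), harvest=date(2020, 3, 2))
        gdd, days = gdd_between_stages(s, phen, "bud_break", "harvest", thresholds_5_30)
        assert (gdd, days) == (pytest.approx(12.0), 1)

    def test_stage_additivity_exact(self, thresholds_5_30):
        rng = np.random.default_rng(3)
        s = make_series(rng.uniform(0, 40, 60 * 24), start="2020-03-01")
        phen = self._phen(
            date(2020, 3, 1), full_bloom=date(2020, 3, 25), harvest=date(2020, 4, 20)
        )
        g1, d1 = gdd_between_stages(s, phen, "bud_break", "full_bloom", thresholds_5_30)
        g2, d2 = gdd_between_stages(s, phen, "full_bloom", "harvest", thresholds_5_30)
        g, d = gdd_between_stages(s, phen, "bud_break", "harvest", thresholds_5_30)
        assert d1 + d2 == d
        assert g1 + g2 == pytest.approx(g, abs=1e-9)

    def test_missing_stage_raises(self, thresholds_5_30):
        from thermaltime.phenology import StageError

        s = constant_series(17.0, 3, start="2020-03-01")
        with pytest.raises(StageError):
            gdd_between_stages(
                s, self._phen(date(2020, 3, 1)), "bud_break", "harvest", thresholds_5_30
            )


class TestEngineProperties:
    def test_equivalence_with_brute_force_oracle(self, random_series_30d, thresholds_5_30):
        for s in random_series_30d:
            start = s.start.date()
            end = start + timedelta(days=29)
            acc = accumulate(s, start, end, thresholds_5_30)
            oracle = brute_force_total(s.data.to_numpy(), 5.0, 30.0)
            assert acc.total == pytest.approx(oracle, abs=1e-9)

    def test_equivalence_uncapped(self, random_series_30d):
        thr = ThermalThresholds(t_base=8.0)
        s = random_series_30d[0]
        start = s.start.date()
        acc = accumulate(s, start, start + timedelta(days=29), thr)
        assert acc.total == pytest.approx(
            brute_force_total(s.data.to_numpy(), 8.0, None), abs=1e-9
        )

    @given(
        tb=st.floats(-5, 15),
        dtb=st.floats(0.1, 5),
        tu=st.floats(25, 40),
        dtu=st.floats(0.1, 5),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_monotone_in_thresholds(self, tb, dtb, tu, dtu, random_series_30d):
        """Total GDD falls as T_b rises and rises as T_u rises."""
        s = random_series_30d[1]
        start = s.start.date()
        end = start + timedelta(days=29)

        def total(t_base, t_upper):
            return accumulate(s, start, end, ThermalThresholds(t_base, t_upper)).total

        assert total(tb + dtb, tu) <= total(tb, tu) + 1e-9
        assert total(tb, tu + dtu) >= total(tb, tu) - 1e-9
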