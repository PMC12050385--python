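"""Season detection, daily expenditure, and seasonal survival budgets."""

import numpy as np
import pandas as pd
import pytest

import hiberniche as hn
from conftest import block_winter, constant_winter


class TestSeasonDetection:
    def test_warm_winter_has_no_season(self):
        assert hn.detect_hibernation_season(constant_winter(10.0)) is None

    def test_cold_block_boundaries_near_block_edges(self):
        series = block_winter(0.0, 10.0, "2015-11-01", "2016-03-01")
        season = hn.detect_hibernation_season(series)
        assert season is not None
        half = hn.SeasonParams().smoothing_days // 2 + 1
        assert abs((season.start_date - pd.Timestamp("2015-11-01")).days) <= half
        assert abs((season.end_date - pd.Timestamp("2016-03-01")).days) <= half
        assert season.duration == pytest.approx(122, abs=2 * half)

    def test_thirteen_cold_days_insufficient(self):
        series = block_winter(0.0, 10.0, "2016-01-01", "2016-01-13")
        assert hn.detect_hibernation_season(series) is None

    def test_fourteen_cold_days_sufficient(self):
        series = block_winter(0.0, 10.0, "2016-01-01", "2016-01-14")
        assert hn.detect_hibernation_season(series) is not None

    def test_gappy_series_rejected(self):
        series = constant_winter(0.0)
        with pytest.raises(ValueError, match="gap"):
            hn.TemperatureSeries(
                location_id="x", winter_year=2015,
                dates=series.dates.delete(40), ta=series.ta[:-1],
            )

    def test_season_mean_temperature(self):
        series = block_winter(-2.0, 10.0, "2015-11-01", "2016-03-01")
        season = hn.detect_hibernation_season(series)
        # boundary days may include a few warm-edge days; mean stays near -2
        assert season.mean_ta == pytest.approx(-2.0, abs=1.0)


class TestDailyExpenditure:
    def test_worked_example_solitary_uninsulated(
        self, ref_state_model, ref_curves, ep_solitary_uninsulated
    ):
        kj, fat = hn.daily_expenditure(
            ref_state_model, ref_curves, -5.0, ep_solitary_uninsulated
        )
        assert kj == pytest.approx(36.1, abs=0.05)
        assert fat == pytest.approx(0.958, abs=1.5e-3)

    def test_worked_example_with_corrections(
        self, ref_state_model, ref_curves, ep_default
    ):
        _, fat = hn.daily_expenditure(ref_state_model, ref_curves, -5.0, ep_default)
        assert fat == pytest.approx(0.237, rel=0.15)

    def test_huddling_exactly_halves_below_t_min(
        self, ref_state_model, ref_curves
    ):
        ep_half = hn.EnergyParams(huddling_factor=0.5, uninsulated=True)
        ep_full = hn.EnergyParams(huddling_factor=1.0, uninsulated=True)
        for ta in (-10.0, -5.0, 0.0, 4.0):  # all below t_min = 4.5
            kj_half, _ = hn.daily_expenditure(ref_state_model, ref_curves, ta, ep_half)
            kj_full, _ = hn.daily_expenditure(ref_state_model, ref_curves, ta, ep_full)
            assert kj_half == pytest.approx(kj_full / 2)

    def test_huddling_spares_conforming_torpor(self, ref_state_model, ref_curves):
        # above t_min only normothermy is thermoregulating, so halving the
        # huddling factor less than halves the total
        ep_half = hn.EnergyParams(huddling_factor=0.5, uninsulated=True)
        ep_full = hn.EnergyParams(huddling_factor=1.0, uninsulated=True)
        kj_half, _ = hn.daily_expenditure(ref_state_model, ref_curves, 6.0, ep_half)
        kj_full, _ = hn.daily_expenditure(ref_state_model, ref_curves, 6.0, ep_full)
        assert kj_full / 2 < kj_half < kj_full

    def test_insulation_reduces_cost_at_cold_temperatures(
        self, ref_state_model, ref_curves
    ):
        warm = hn.EnergyParams(solitary=True)
        cold = hn.EnergyParams(solitary=True, uninsulated=True)
        for ta in (-15.0, -10.0, -5.0):
            kj_ins, _ = hn.daily_expenditure(ref_state_model, ref_curves, ta, warm)
            kj_no, _ = hn.daily_expenditure(ref_state_model, ref_curves, ta, cold)
            assert kj_ins < kj_no

    def test_hours_conservation(self, ref_state_model):
        mn, mt = hn.state_minutes(ref_state_model, -7.3)
        assert (float(mn) + float(mt)) / 60.0 == pytest.approx(24.0)


def _oracle_budget(series, season, sm, tc, ep):
    """Independent single-loop reimplementation of the cumulative budget."""
    total, death = 0.0, None
    d = season.start_date
    while d <= season.end_date:
        ta = float(series.ta[series.dates == d][0])
        t_eff = ta + (0.0 if ep.uninsulated else ep.insulation_offset)
        p = float(hn.predict_p_normothermy(sm, t_eff))
        hn_hours = 24.0 * p
        f_n = 1.0 if ep.solitary else ep.huddling_factor
        f_t = 1.0 if (ep.solitary or t_eff >= tc.t_min) else ep.huddling_factor
        kj = hn_hours * hn.predict_mr(tc, t_eff, "normothermy") * f_n
        kj += (24.0 - hn_hours) * hn.predict_mr(tc, t_eff, "torpor") * f_t
        total += kj / ep.fat_energy_density
        if death is None and total > ep.fat_budget:
            death = d
        d += pd.Timedelta(days=1)
    return total, death


class TestSeasonBudget:
    def test_matches_bruteforce_oracle_on_random_winters(
        self, ref_state_model, ref_curves, ep_default
    ):
        rng_seeds = range(40)
        checked = 0
        for seed in rng_seeds:
            cfg = hn.ClimateSimConfig(
                annual_mean=float(5 + (seed % 7)), amplitude=12.0,
                years=range(2000, 2001), seed=seed,
            )
            series = hn.simulate_daily_temperature(cfg)[0]
            season = hn.detect_hibernation_season(series)
            if season is None:
                continue
            traj = hn.season_budget(series, season, ref_state_model, ref_curves,
                                    ep_default)
            total, death = _oracle_budget(series, season, ref_state_model,
                                          ref_curves, ep_default)
            assert traj.total_fat_g == pytest.approx(total, abs=1e-9)
            assert traj.death_date == death
            checked += 1
        assert checked >= 20

    def test_mild_short_season_survives(
        self, ref_state_model, ref_curves, ep_solitary_uninsulated
    ):
        series = block_winter(6.0, 10.0, "2015-12-01", "2016-01-15")
        season = hn.detect_hibernation_season(series)
        traj = hn.season_budget(series, season, ref_state_model, ref_curves,
                                ep_solitary_uninsulated)
        assert traj.survived
        assert traj.total_fat_g < 27.0

    def test_cumulative_fat_non_decreasing(
        self, ref_state_model, ref_curves, ep_default
    ):
        series = block_winter(-8.0, 10.0, "2015-11-15", "2016-02-15")
        season = hn.detect_hibernation_season(series)
        traj = hn.season_budget(series, season, ref_state_model, ref_curves,
                                ep_default)
        assert np.all(np.diff(traj.cumulative_fat_g) >= 0)
        assert traj.survived == (traj.death_date is None)

    def test_death_on_first_crossing_day(
        self, ref_state_model, ref_curves, ep_solitary_uninsulated
    ):
        series = block_winter(-10.0, 10.0, "2015-11-15", "2016-02-15")
        season = hn.detect_hibernation_season(series)
        traj = hn.season_budget(series, season, ref_state_model, ref_curves,
                                ep_solitary_uninsulated)
        assert not traj.survived
        i = list(traj.dates).index(traj.death_date)
        assert traj.cumulative_fat_g[i] > 27.0
        assert np.all(traj.cumulative_fat_g[:i] <= 27.0)


class TestTorporOnlyComparison:
    def test_torpor_only_never_exceeds_full_budget(
        self, ref_state_model, ref_curves, ep_default
    ):
        series = block_winter(-6.0, 10.0, "2015-11-01", "2016-03-01")
        season = hn.detect_hibernation_season(series)
        full = hn.season_budget(series, season, ref_state_model, ref_curves,
                                ep_default)
        torpor_only = hn.budget_without_normothermy(series, season, ref_curves,
                                                    ep_default)
        assert np.all(torpor_only.fat_g_per_day <= full.fat_g_per_day + 1e-12)

    def test_severe_winter_contrast(self, ref_state_model, ref_curves,
                                    ep_solitary_uninsulated):
        """Full model predicts death; the torpor-only simplification predicts
        survival on the same winter — the qualitative failure mode of
        torpor-only energy budgets."""
        series = block_winter(-9.0, 10.0, "2015-12-01", "2015-12-20")
        season = hn.detect_hibernation_season(series)
        full = hn.season_budget(series, season, ref_state_model, ref_curves,
                                ep_solitary_uninsulated)
        torpor_only = hn.budget_without_normothermy(
            series, season, ref_curves, ep_solitary_uninsulated
        )
        assert not full.survived
        assert torpor_only.survived

    def test_relative_gap_largest_at_warm_edge(
        self, ref_state_model, ref_curves, ep_solitary_uninsulated
    ):
        """Normothermy probability (and hence the torpor-only underestimate)
        is highest at the warm edge of the hibernation range."""
        tas = np.linspace(-15.0, 6.9, 45)
        ratios = []
        for ta in tas:
            full_kj, _ = hn.daily_expenditure(
                ref_state_model, ref_curves, ta, ep_solitary_uninsulated
            )
            torpor_kj = 24.0 * hn.predict_mr(ref_curves, ta, "torpor")
            ratios.append(full_kj / torpor_kj)
        assert np.argmax(ratios) == len(ratios) - 1


class TestEnergyParams:
    def test_budget_from_masses(self):
        assert hn.EnergyParams.from_masses(46.0, 19.0).fat_budget == 27.0

    def test_invalid_huddling_rejected(self):
        with pytest.raises(ValueError):
            hn.EnergyParams(huddling_factor=0.0)

    def test_invalid_season_params_rejected(self):
        with pytest.raises(ValueError):
            hn.SeasonParams(min_season_days=0)
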