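"""Driver-layer computations against closed forms and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from landsea import drivers as drv


class TestFishBiomass:
    def test_single_fish_arithmetic(self):
        # 0.01 * 10^3 = 10 g over 10,000 m^2 (1 ha) -> 0.01 kg/ha
        obs = [drv.FishObservation("sp", 1, 10.0, 0.01, 3.0, 10000.0)]
        assert drv.fish_biomass(obs) == pytest.approx(0.01)

    def test_zero_length_contributes_nothing(self):
        obs = [
            drv.FishObservation("sp", 1, 0.0, 0.01, 3.0, 125.0),
            drv.FishObservation("sp2", 2, 10.0, 0.01, 3.0, 125.0),
        ]
        only_second = [obs[1]]
        assert drv.fish_biomass(obs) == pytest.approx(drv.fish_biomass(only_second))

    def test_matches_per_fish_loop_oracle(self, rng):
        # mixed school over a 125 m^2 belt: independent per-fish summation
        species = [("a", 0.012, 3.1), ("b", 0.025, 2.9), ("c", 0.018, 3.0)]
        obs = []
        total_g = 0.0
        for sp, a, b in species:
            for _ in range(5):
                tl = float(rng.uniform(5, 40))
                cnt = int(rng.integers(1, 4))
                obs.append(drv.FishObservation(sp, cnt, tl, a, b, 125.0))
                total_g += cnt * a * tl**b
        expect = total_g / 125.0 * 10.0
        assert drv.fish_biomass(obs) == pytest.approx(expect, rel=1e-12)

    def test_guild_filter_and_exclusions(self):
        obs = [
            drv.FishObservation("s", 1, 20.0, 0.02, 3.0, 125.0, guild="scraper"),
            drv.FishObservation("g", 1, 20.0, 0.02, 3.0, 125.0, guild="grazer"),
            drv.FishObservation("x", 1, 20.0, 0.02, 3.0, 125.0, guild="other", excluded=True),
        ]
        total = drv.fish_biomass(obs)
        scraper = drv.fish_biomass(obs, "scraper")
        herb = drv.fish_biomass(obs, "herbivore")
        assert scraper == pytest.approx(total / 2)
        assert herb == pytest.approx(total)

    def test_missing_length_weight_constant_names_species(self):
        with pytest.raises(ValueError, match="humuhumu"):
            drv.FishObservation("humuhumu", 1, 10.0, float("nan"), 3.0, 125.0)


class TestDispersalKernel:
    def test_closed_form_values(self):
        assert drv.dispersal_weight(0.0) == pytest.approx(1.0)
        assert drv.dispersal_weight(2000.0) == pytest.approx(np.exp(-4.5), abs=1e-9)
        sigma = 2000.0 / 3.0
        assert drv.dispersal_weight(sigma) == pytest.approx(np.exp(-0.5))

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            drv.dispersal_weight(-1.0)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        d1=st.floats(0, 5000),
        d2=st.floats(0, 5000),
    )
    def test_monotone_decreasing_and_bounded(self, d1, d2):
        lo, hi = sorted([d1, d2])
        w_lo, w_hi = drv.dispersal_weight(lo), drv.dispersal_weight(hi)
        assert 0.0 < w_hi <= w_lo <= 1.0


class TestWastewaterAndNutrients:
    def test_no_sources_all_zero(self):
        out = drv.wastewater_load([], n_cells=10)
        assert (out[["effluent_l_ha_yr", "nitrogen_kg_ha_yr"]].to_numpy() == 0).all()

    def test_kernel_ratio_between_cells(self):
        src = [drv.PointSource("OSDS", entry_cell=0, effluent_l_yr=1000.0)]
        out = drv.wastewater_load(src, n_cells=21, cell_length_m=100.0)
        near = out.effluent_l_ha_yr.iloc[0]
        far = out.effluent_l_ha_yr.iloc[20]  # 2,000 m alongshore
        assert near == pytest.approx(1000.0)
        assert far / near == pytest.approx(np.exp(-4.5), rel=1e-9)

    def test_travel_time_flag_excludes_source(self):
        src = [
            drv.PointSource("OSDS", 0, effluent_l_yr=500.0, within_one_year_travel=False)
        ]
        out = drv.wastewater_load(src, n_cells=5)
        assert (out.effluent_l_ha_yr == 0).all()

    def test_golf_course_printed_constants(self):
        # 1 ha at the shoreline: 585 kg/ha * 32% leaching = 187.2 kg delivered
        golf = [drv.PointSource("golf", entry_cell=0, area_ha=1.0, inland_distance_m=0.0)]
        out = drv.nutrient_input(np.zeros(1), golf)
        assert out[0] == pytest.approx(585.0 * 0.32)

    def test_inland_decay_strictly_reduces_delivery(self):
        near = drv.nutrient_input(
            np.zeros(1), [drv.PointSource("golf", 0, area_ha=2.0, inland_distance_m=100.0)]
        )[0]
        far = drv.nutrient_input(
            np.zeros(1), [drv.PointSource("golf", 0, area_ha=2.0, inland_distance_m=2500.0)]
        )[0]
        assert far < near

    def test_linearity_in_source_load(self):
        src1 = [drv.PointSource("OSDS", 3, effluent_l_yr=100.0)]
        src2 = [drv.PointSource("OSDS", 3, effluent_l_yr=300.0)]
        o1 = drv.wastewater_load(src1, 8).effluent_l_ha_yr
        o2 = drv.wastewater_load(src2, 8).effluent_l_ha_yr
        assert np.allclose(o2, 3 * o1)


class TestUrbanRunoff:
    def test_linear_interpolation_between_snapshots(self):
        snaps = {2010: np.array([100.0]), 2014: np.array([200.0])}
        out = drv.urban_runoff(snaps, [2012]).set_index("cell")
        assert out.loc[0, 2012] == pytest.approx(150.0)

    def test_constant_extrapolation_and_equal_snapshots(self):
        snaps = {2010: np.array([50.0]), 2014: np.array([50.0])}
        out = drv.urban_runoff(snaps, [2005, 2012, 2020]).set_index("cell")
        assert (out.loc[0] == 50.0).all()

    def test_uneven_snapshots_match_interp_oracle(self):
        years = [2001, 2006, 2017]
        vals = [10.0, 40.0, 20.0]
        snaps = {y: np.array([v]) for y, v in zip(years, vals)}
        out = drv.urban_runoff(snaps, range(2000, 2020)).set_index("cell")
        expect = np.interp(range(2000, 2020), years, vals)
        assert np.allclose(out.loc[0].to_numpy(), expect)

    def test_single_snapshot_rejected(self):
        with pytest.raises(ValueError):
            drv.urban_runoff({2010: np.array([1.0])}, [2010])


class TestRainfall:
    def test_constant_series(self):
        annual, peak = drv.rainfall_metrics(np.ones(365))
        assert annual == 365.0 and peak == 3.0

    def test_single_spike(self):
        x = np.zeros(365)
        x[100] = 30.0
        assert drv.rainfall_metrics(x)[1] == 30.0

    def test_window_scan_oracle(self):
        x = np.zeros(365)
        x[:6] = [5, 1, 1, 9, 9, 9]
        annual, peak = drv.rainfall_metrics(x)
        assert peak == 27.0 and annual == 34.0

    def test_missing_days_listed(self):
        x = np.ones(365)
        x[17] = np.nan
        with pytest.raises(ValueError, match="17"):
            drv.rainfall_metrics(x)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(0, 2**32 - 1))
    def test_peak_bounds(self, seed):
        x = np.random.default_rng(seed).gamma(0.5, 2.0, 365)
        annual, peak = drv.rainfall_metrics(x)
        assert peak <= annual + 1e-9
        assert peak >= x.max() - 1e-9


class TestSediment:
    def test_power_law_ratios(self):
        q = {2000: 0.5, 2001: 1.0, 2002: 2.0}
        out = drv.sediment_input(10.0, q, beta=2.0)
        ratios = out / out[2001]
        assert np.allclose(ratios.to_numpy(), [0.25, 1.0, 4.0])

    def test_constant_discharge_gives_longterm_mean(self):
        out = drv.sediment_input(42.0, {y: 3.0 for y in range(2000, 2010)}, beta=1.5)
        assert np.allclose(out.to_numpy(), 42.0)

    def test_rescaling_preserves_longterm_mean(self, rng):
        q = {2000 + i: float(v) for i, v in enumerate(rng.lognormal(0, 1, 12))}
        out = drv.sediment_input(7.5, q, beta=1.5)
        assert out.mean() == pytest.approx(7.5)

    def test_all_zero_discharge_rejected(self):
        with pytest.raises(ValueError):
            drv.sediment_input(1.0, {2000: 0.0, 2001: 0.0})


class TestSstSummary:
    def test_constant_series(self):
        s = drv.ThermalStressSeries(np.full(365, 26.0))
        mean, sd = drv.sst_summary(s)
        assert mean == 26.0 and sd == 0.0

    def test_sinusoid_window_position(self):
        # smooth seasonal cycle peaking at day 200 (1-based): the 90-day
        # window runs days 156-245, i.e. mean of those days
        t = np.arange(365)
        x = 25 + 2 * np.cos(2 * np.pi * (t - 199) / 365.0)
        s = drv.ThermalStressSeries(x)
        mean, _ = drv.sst_summary(s)
        assert mean == pytest.approx(x[155:245].mean(), abs=1e-9)

    def test_tie_break_takes_earliest_peak(self):
        x = np.full(200, 20.0)
        x[40:47] = 25.0  # first plateau
        x[140:147] = 25.0  # identical later plateau
        s = drv.ThermalStressSeries(x)
        mean, _ = drv.sst_summary(s)
        lo, hi = 43 - 44, 43 + 46  # centred on the first plateau, truncated at 0
        assert mean == pytest.approx(x[max(lo, 0) : hi].mean())


class TestDHW:
    def test_no_hotspot_no_stress(self):
        s = drv.ThermalStressSeries(np.full(120, 27.0), mmm=27.0)
        assert drv.dhw(s) == 0.0

    def test_two_degree_twelve_weeks(self):
        s = drv.ThermalStressSeries(np.full(84, 29.0), mmm=27.0)
        assert drv.dhw(s) == pytest.approx(24.0)

    def test_sub_degree_hotspots_do_not_accumulate(self):
        s = drv.ThermalStressSeries(np.full(120, 27.5), mmm=27.0)
        assert drv.dhw(s) == 0.0

    def test_missing_mmm_rejected(self):
        with pytest.raises(ValueError, match="MMM"):
            drv.dhw(drv.ThermalStressSeries(np.full(120, 27.0)))

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.floats(-5, 5), st.integers(0, 2**32 - 1))
    def test_translation_covariance(self, shift, seed):
        sst = 27.0 + np.random.default_rng(seed).normal(0, 1.5, 150)
        a = drv.dhw(drv.ThermalStressSeries(sst, mmm=27.0))
        b = drv.dhw(drv.ThermalStressSeries(sst + shift, mmm=27.0 + shift))
        assert a == pytest.approx(b, abs=1e-9)


class TestWavePower:
    def test_constant_and_zero(self):
        assert drv.wave_power_metric(np.full(365, 10.0)) == 10.0
        assert drv.wave_power_metric(np.zeros(365)) == 0.0

    def test_upper_tail_oracle(self):
        x = np.arange(1.0, 366.0)
        thr = np.quantile(x, 0.975, method="linear")
        expect = x[x >= thr].mean()
        assert drv.wave_power_metric(x) == pytest.approx(expect)


class TestPopulationAndGear:
    def test_geometric_enumeration_oracle(self, rng):
        xy = rng.uniform(0, 30000, size=(400, 2))
        pop = np.ones(400)
        centre = (15000.0, 15000.0)
        expect = int(np.sum(np.hypot(xy[:, 0] - 15000, xy[:, 1] - 15000) <= 15000))
        assert drv.population_within(xy, pop, centre) == expect

    def test_linearity(self, rng):
        xy = rng.uniform(0, 30000, size=(50, 2))
        pop = rng.lognormal(3, 1, 50)
        c = (0.0, 0.0)
        assert drv.population_within(xy, 2 * pop, c) == pytest.approx(
            2 * drv.population_within(xy, pop, c)
        )

    def test_interpolate_years(self):
        out = drv.interpolate_years({2000: 10.0, 2005: 20.0}, range(2000, 2006))
        assert out[2002] == pytest.approx(14.0)

    @pytest.mark.parametrize(
        "flags,rank",
        [
            (dict(no_take=True), 1),
            (dict(lay_net=True, spear=True, aquarium=True), 2),
            (dict(lay_net=True, aquarium=True), 3),
            (dict(lay_net=True), 4),
            (dict(aquarium=True), 5),
            (dict(), 6),
        ],
    )
    def test_printed_rank_ordering(self, flags, rank):
        assert drv.gear_rank(**flags) == rank

    def test_contradictory_flags(self):
        with pytest.raises(ValueError):
            drv.gear_rank(no_take=True, open_access=True)
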