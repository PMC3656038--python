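"""Tests for Monte Carlo upscaling and decadal stock accounting."""

import numpy as np
import pandas as pd
import pytest

import soilcarbon as sc
from soilcarbon.errors import InputError, UndefinedStatisticError
from soilcarbon.regional import DecadeRecord, RegionalSummary
from soilcarbon.reference import (
    published_belt_summary,
    published_region_summaries,
)
from soilcarbon.synthetic import SyntheticSpec, gen_region_set


def _tiny_region(seed=0, n_years=20, n_cells=4):
    spec = SyntheticSpec(seed=seed, n_years=n_years, n_soil_cells=n_cells)
    return gen_region_set(spec)[0]


def _summary(name, area, changes, densities=None, initial=30.0):
    densities = densities or [25.0] * len(changes)
    return RegionalSummary(
        name=name,
        area_mha=area,
        initial_density=initial,
        decades=tuple(
            DecadeRecord(label=f"{1960 + 10 * i}s", density=d, c_input=1.0, change_tg=c)
            for i, (c, d) in enumerate(zip(changes, densities))
        ),
    )


class TestSampling:
    def test_single_cell_grid_always_returns_it(self):
        grid = pd.DataFrame({"cell_id": [0], "soc_Mg_ha": [29.5]})
        rng = np.random.default_rng(0)
        for _ in range(10):
            assert sc.sample_soil_state(grid, rng)["soc_Mg_ha"] == 29.5

    def test_cells_drawn_uniformly(self):
        grid = pd.DataFrame({"cell_id": range(4), "soc_Mg_ha": [20.0, 25.0, 30.0, 35.0]})
        rng = np.random.default_rng(1)
        draws = [sc.sample_soil_state(grid, rng)["cell_id"] for _ in range(10_000)]
        counts = np.bincount(np.array(draws, dtype=int), minlength=4)
        # 3σ binomial band around n/4
        sigma = np.sqrt(10_000 * 0.25 * 0.75)
        assert np.all(np.abs(counts - 2500) < 3 * sigma)

    def test_fixed_seed_reproduces_draws(self):
        grid = pd.DataFrame({"cell_id": range(10), "soc_Mg_ha": np.arange(10.0)})
        a = [sc.sample_soil_state(grid, np.random.default_rng(7))["cell_id"] for _ in range(1)]
        b = [sc.sample_soil_state(grid, np.random.default_rng(7))["cell_id"] for _ in range(1)]
        assert a == b

    def test_input_scale_support_and_degeneracy(self):
        rng = np.random.default_rng(2)
        assert sc.sample_input_scale(rng, 0.0) == 1.0
        draws = np.array([sc.sample_input_scale(rng, 0.1) for _ in range(5000)])
        assert draws.min() >= 0.9 and draws.max() <= 1.1
        assert draws.mean() == pytest.approx(1.0, abs=0.005)


class TestRunRegion:
    def test_zero_yields_give_strictly_decreasing_soc(self):
        region = _tiny_region()
        region.yields = np.zeros_like(region.yields)
        run = sc.run_region(region, spinup_years=5)
        assert np.all(np.diff(run.annual_soc) < 0)

    def test_deterministic(self):
        region = _tiny_region()
        a = sc.run_region(region, spinup_years=5)
        b = sc.run_region(region, spinup_years=5)
        np.testing.assert_array_equal(a.annual_soc, b.annual_soc)

    def test_area_scales_stocks_not_densities(self):
        region = _tiny_region()
        run = sc.run_region(region, spinup_years=5)
        s1 = sc.decadal_summary(run.annual_soc, run.annual_c_input, region.area_mha)
        s2 = sc.decadal_summary(run.annual_soc, run.annual_c_input, 2 * region.area_mha)
        assert s2.total_change_tg == pytest.approx(2 * s1.total_change_tg, rel=1e-12)
        assert [d.density for d in s1.decades] == [d.density for d in s2.decades]


class TestMonteCarlo:
    def test_degenerate_ensemble_collapses(self):
        region = _tiny_region(n_cells=1)
        cfg = sc.McConfig(n_runs=8, input_halfwidth=0.0, seed=3)
        mc = sc.monte_carlo_region(region, cfg=cfg, spinup_years=5)
        assert np.all(mc.ci_hi == mc.ci_lo)
        det = sc.run_region(
            region,
            spinup_years=5,
            initial_soc=float(region.soil_grid["soc_Mg_ha"].iloc[0]),
        )
        np.testing.assert_allclose(mc.mean_soc, det.annual_soc, rtol=1e-12)

    def test_mean_input_run_inside_ci(self):
        region = _tiny_region()
        cfg = sc.McConfig(n_runs=300, input_halfwidth=0.1, seed=4)
        mc = sc.monte_carlo_region(region, cfg=cfg, spinup_years=10)
        det = sc.run_region(region, spinup_years=10)
        assert np.all(det.annual_soc >= mc.ci_lo - 1e-9)
        assert np.all(det.annual_soc <= mc.ci_hi + 1e-9)

    def test_same_seed_bit_identical(self):
        region = _tiny_region()
        cfg = sc.McConfig(n_runs=12, seed=5)
        a = sc.monte_carlo_region(region, cfg=cfg, spinup_years=3)
        b = sc.monte_carlo_region(region, cfg=cfg, spinup_years=3)
        np.testing.assert_array_equal(a.soc, b.soc)
        np.testing.assert_array_equal(a.input_scales, b.input_scales)


class TestDecadalSummary:
    def test_unit_identity_mg_ha_times_mha_is_tg(self):
        # a 6.4 Mg ha⁻¹ drop over 10 Mha is −64 Tg
        soc = np.concatenate([np.linspace(30.0, 23.6, 11)])
        summary = sc.decadal_summary(soc, np.ones(10), area_mha=10.0)
        assert summary.total_change_tg == pytest.approx(-64.0, rel=1e-12)

    def test_flat_series_has_zero_changes(self):
        summary = sc.decadal_summary(np.full(21, 25.0), np.ones(20), 5.0)
        assert all(d.change_tg == 0.0 for d in summary.decades)

    def test_decades_telescope_to_total(self, rng):
        soc = 30.0 + np.cumsum(rng.normal(-0.1, 0.05, 51))
        soc = np.concatenate([[30.0], soc])[:51]
        summary = sc.decadal_summary(soc, np.ones(50), 7.0)
        assert summary.total_change_tg == pytest.approx(
            (soc[50] - soc[0]) * 7.0, rel=1e-9
        )

    def test_partial_decade_rejected(self):
        with pytest.raises(InputError):
            sc.decadal_summary(np.ones(16), np.ones(15), 1.0)


class TestAggregation:
    def test_published_region_areas_sum_to_belt(self):
        belt = sc.aggregate_belt(published_region_summaries())
        assert belt.area_mha == pytest.approx(15.08, abs=1e-12)

    def test_single_region_identity(self):
        s = _summary("A", 2.0, [-5.0, -3.0])
        belt = sc.aggregate_belt([s], name="A")
        assert belt.total_change_tg == s.total_change_tg
        assert belt.area_mha == s.area_mha
        assert [d.density for d in belt.decades] == [d.density for d in s.decades]

    def test_stock_changes_add_and_densities_area_weight(self):
        a = _summary("A", 1.0, [-2.0], densities=[20.0])
        b = _summary("B", 3.0, [-6.0], densities=[28.0])
        belt = sc.aggregate_belt([a, b])
        assert belt.decades[0].change_tg == pytest.approx(-8.0)
        assert belt.decades[0].density == pytest.approx((20.0 + 3 * 28.0) / 4.0)

    def test_permutation_invariant(self):
        regions = published_region_summaries()
        fwd = sc.aggregate_belt(regions)
        rev = sc.aggregate_belt(regions[::-1])
        assert fwd.total_change_tg == pytest.approx(rev.total_change_tg, rel=1e-12)
        assert fwd.area_mha == pytest.approx(rev.area_mha, rel=1e-12)

    def test_duplicate_names_rejected(self):
        s = _summary("A", 1.0, [-1.0])
        with pytest.raises(InputError):
            sc.aggregate_belt([s, s])

    def test_belt_aggregate_matches_published_belt_row(self):
        belt = sc.aggregate_belt(published_region_summaries())
        printed = published_belt_summary()
        for ours, theirs in zip(belt.decades, printed.decades):
            assert ours.change_tg == pytest.approx(theirs.change_tg, abs=1e-9)
            assert ours.change_ci[0] == pytest.approx(theirs.change_ci[0], abs=1e-9)
            assert ours.change_ci[1] == pytest.approx(theirs.change_ci[1], abs=1e-9)


class TestLossRatesAndShares:
    def test_published_decadal_rates(self):
        rates = sc.loss_rates_and_shares(published_belt_summary())
        assert rates.rates_tg_per_yr == pytest.approx((6.4, 3.7, 2.5, 1.4, 1.6))
        assert rates.total_change_tg == pytest.approx(-156.0)
        assert rates.mean_annual_rate_tg_per_yr == pytest.approx(3.12)

    def test_first_three_decades_share(self):
        rates = sc.loss_rates_and_shares(published_belt_summary())
        assert rates.share_of_first(3) == pytest.approx(100 * 126 / 156, rel=1e-9)

    def test_equal_decades_have_equal_shares(self):
        s = _summary("A", 1.0, [-4.0, -4.0, -4.0])
        rates = sc.loss_rates_and_shares(s)
        assert rates.shares_pct == pytest.approx((100 / 3,) * 3)

    def test_zero_total_change_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            sc.loss_rates_and_shares(_summary("A", 1.0, [1.0, -1.0]))

    def test_queensland_density_decline(self):
        qld = next(s for s in published_region_summaries() if s.name == "QLD")
        assert qld.density_decline == pytest.approx(13.0)
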