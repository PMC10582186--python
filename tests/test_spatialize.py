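"""Population calibration and proxy-based EDI allocation on grids."""

import numpy as np
import pandas as pd
import pytest

from mehgrid import spatialize as sp
from mehgrid.io import NO_ZONE, GridGeometry

ND = -9999.0


def _zones():
    # two counties side by side on a 2×4 grid, one outside column
    z = np.array([[1, 1, 2, NO_ZONE], [1, 1, 2, NO_ZONE]], dtype=int)
    return z


class TestCleanPopulation:
    def test_in_zone_nulls_become_zero(self):
        z = _zones()
        g = np.array([[1.0, ND, 3.0, ND], [np.nan, 2.0, ND, 5.0]])
        out = sp.clean_population(g, z, ND)
        assert out[0, 1] == 0.0 and out[1, 0] == 0.0 and out[1, 2] == 0.0
        assert out[0, 0] == 1.0 and out[1, 1] == 2.0
        # outside zones stays nodata even when a value was present
        assert out[0, 3] == ND and out[1, 3] == ND

    def test_all_null_county_becomes_all_zero(self):
        z = np.ones((2, 2), dtype=int)
        out = sp.clean_population(np.full((2, 2), ND), z, ND)
        assert (out == 0.0).all()

    def test_no_nulls_is_identity(self):
        z = np.ones((2, 2), dtype=int)
        g = np.arange(4.0).reshape(2, 2) + 1
        np.testing.assert_array_equal(sp.clean_population(g, z, ND), g)

    def test_negative_population_rejected(self):
        z = np.ones((1, 2), dtype=int)
        with pytest.raises(ValueError, match="negative"):
            sp.clean_population(np.array([[1.0, -2.0]]), z, ND)


class TestCalibratePopulation:
    def test_scales_to_official_total(self):
        z = np.ones((1, 2), dtype=int)
        out = sp.calibrate_population(np.array([[1.0, 3.0]]), z, pd.Series({1: 8.0}), ND)
        np.testing.assert_allclose(out, [[2.0, 6.0]])

    def test_already_calibrated_unchanged(self):
        z = np.ones((1, 2), dtype=int)
        g = np.array([[2.0, 6.0]])
        out = sp.calibrate_population(g, z, pd.Series({1: 8.0}), ND)
        np.testing.assert_allclose(out, g, rtol=1e-15)

    def test_counties_calibrated_independently(self):
        z = _zones()
        g = sp.clean_population(np.ones((2, 4)), z, ND)
        out = sp.calibrate_population(g, z, pd.Series({1: 40.0, 2: 10.0}), ND)
        assert out[(z == 1)].sum() == pytest.approx(40.0)
        assert out[(z == 2)].sum() == pytest.approx(10.0)
        np.testing.assert_allclose(out[z == 1], 10.0)  # county 2 untouched by 1

    def test_zero_mass_spreads_uniformly(self):
        z = np.ones((1, 4), dtype=int)
        out = sp.calibrate_population(np.zeros((1, 4)), z, pd.Series({1: 8.0}), ND)
        np.testing.assert_allclose(out, 2.0)

    def test_conservation_on_many_counties(self):
        from mehgrid import synthetic_data as sd

        region = sd.make_region(7, 3, (110, 110), seed=11)  # 21 counties, 12100 cells
        inputs = sd.simulate_inputs(region, (2010, 2012), seed=11, include_cells=False)
        official = region.counties.set_index("county")["population"]
        cleaned = sp.clean_population(inputs.population_grid, region.zone_grid, ND)
        cal = sp.calibrate_population(cleaned, region.zone_grid, official, ND)
        diag = sp.conservation_diagnostics(cal, region.zone_grid, official)
        assert len(diag) >= 20
        assert diag["rel_error"].max() <= 1e-9


class TestExpenditure:
    def test_engel_product(self):
        out = sp.expenditure_from_engel(
            pd.Series({1: 10_000.0}), pd.Series({1: 0.35})
        )
        assert out[1] == pytest.approx(3500.0)

    def test_income_ratio_product(self):
        out = sp.expenditure_from_income_ratio(
            county_income=pd.Series({1: 20_000.0}),
            county_city=pd.Series({1: "c"}),
            city_food_expenditure=pd.Series({"c": 3.0}),
            city_income=pd.Series({"c": 10.0}),
        )
        assert out[1] == pytest.approx(6000.0)

    def test_zero_engel_gives_zero(self):
        out = sp.expenditure_from_engel(pd.Series({1: 10_000.0}), pd.Series({1: 0.0}))
        assert out[1] == 0.0

    def test_dispatcher_prefers_engel_then_income(self):
        engel = pd.DataFrame({"total_expenditure": [10_000.0], "engel": [0.35]}, index=[1])
        income = pd.DataFrame(
            {"income": [20_000.0], "city_food_expenditure": [3.0], "city_income": [10.0]},
            index=[2],
        )
        out = sp.estimate_county_expenditure([1, 2], engel, income).set_index("county")
        assert out.loc[1, "pcon"] == 3500.0 and out.loc[1, "method"] == "engel"
        assert out.loc[2, "pcon"] == 6000.0 and out.loc[2, "method"] == "income-ratio"
        with pytest.raises(ValueError, match="neither"):
            sp.estimate_county_expenditure([3], engel, income)


class TestExpenditureGrid:
    def test_scalar_multiply_per_county(self):
        z = np.ones((1, 2), dtype=int)
        out = sp.expenditure_grid(np.array([[2.0, 6.0]]), z, pd.Series({1: 10.0}), ND)
        np.testing.assert_allclose(out, [[20.0, 60.0]])

    def test_missing_pcon_raises(self):
        z = np.ones((1, 2), dtype=int)
        with pytest.raises(KeyError, match="county 1"):
            sp.expenditure_grid(np.ones((1, 2)), z, pd.Series({2: 1.0}), ND)


class TestAllocateEdi:
    def test_share_allocation(self):
        z = np.ones((1, 2), dtype=int)
        out = sp.allocate_edi(pd.Series({1: 0.04}), np.array([[20.0, 60.0]]), z, ND)
        np.testing.assert_allclose(out, [[0.01, 0.03]])

    def test_single_cell_county_gets_everything(self):
        z = np.array([[1]])
        out = sp.allocate_edi(pd.Series({1: 0.07}), np.array([[3.0]]), z, ND)
        assert out[0, 0] == pytest.approx(0.07)

    def test_negative_edi_rejected(self):
        z = np.array([[1]])
        with pytest.raises(ValueError, match="negative"):
            sp.allocate_edi(pd.Series({1: -0.1}), np.ones((1, 1)), z, ND)

    def test_zero_proxy_mass_uniform_fallback(self):
        z = np.ones((1, 4), dtype=int)
        out = sp.allocate_edi(pd.Series({1: 0.08}), np.zeros((1, 4)), z, ND)
        np.testing.assert_allclose(out, 0.02)

    def test_conservation_and_masking(self):
        from mehgrid import synthetic_data as sd

        region = sd.make_region(7, 3, (110, 110), seed=13)
        inputs = sd.simulate_inputs(region, (2010, 2012), seed=13, include_cells=False)
        z = region.zone_grid
        official = region.counties.set_index("county")["population"]
        pcon = inputs.expenditure.set_index("county")["pcon"]
        cleaned = sp.clean_population(inputs.population_grid, z, ND)
        cal = sp.calibrate_population(cleaned, z, official, ND)
        proxy = sp.expenditure_grid(cal, z, pcon, ND)
        edi = pd.Series(
            np.linspace(0.01, 0.09, len(region.county_ids)), index=region.county_ids
        )
        out = sp.allocate_edi(edi, proxy, z, ND)
        diag = sp.conservation_diagnostics(out, z, edi)
        assert diag["rel_error"].max() <= 1e-9
        assert (out[z == NO_ZONE] == ND).all()

    def test_proxy_collapse_under_uniform_expenditure(self):
        """Uniform pCON per county ⇒ expenditure allocation == population shares."""
        rng = np.random.default_rng(2)
        z = _zones()
        pop = sp.clean_population(rng.uniform(1, 10, z.shape), z, ND)
        cal = sp.calibrate_population(pop, z, pd.Series({1: 100.0, 2: 50.0}), ND)
        # a power-of-two uniform level keeps the equality exact in float
        pcon = pd.Series({1: 8.0, 2: 8.0})
        proxy = sp.expenditure_grid(cal, z, pcon, ND)
        edi = pd.Series({1: 0.03, 2: 0.05})
        by_exp = sp.allocate_edi(edi, proxy, z, ND)
        by_pop = sp.allocate_edi(edi, cal, z, ND)
        in_zone = z != NO_ZONE
        np.testing.assert_array_equal(by_exp[in_zone], by_pop[in_zone])


class TestRunSpatialization:
    def _setup(self):
        from mehgrid import synthetic_data as sd

        region = sd.make_region(2, 2, (10, 10), seed=17)
        inputs = sd.simulate_inputs(region, (2010, 2012), seed=17, include_cells=False)
        years = [2010, 2011, 2012]
        edi = pd.DataFrame(
            [
                {"county": c, "year": y, "edi": 0.01 * c}
                for c in region.county_ids
                for y in years
            ]
        )
        return region, inputs, edi

    def test_linearity_in_inventory(self):
        region, inputs, edi = self._setup()
        kw = dict(
            zones=region.zone_grid,
            population_grids=inputs.population_grid,
            official_population=region.counties.set_index("county")["population"],
            pcon=inputs.expenditure.set_index("county")["pcon"],
            geometry=region.geometry,
        )
        base = sp.run_spatialization(edi, **kw)
        double = sp.run_spatialization(edi.assign(edi=2 * edi["edi"]), **kw)
        for key in base:
            in_zone = region.zone_grid != NO_ZONE
            np.testing.assert_allclose(
                double[key][in_zone], 2 * base[key][in_zone], rtol=1e-12
            )

    def test_missing_year_raises(self):
        region, inputs, edi = self._setup()
        with pytest.raises(KeyError, match="2013"):
            sp.run_spatialization(
                edi,
                region.zone_grid,
                inputs.population_grid,
                region.counties.set_index("county")["population"],
                inputs.expenditure.set_index("county")["pcon"],
                region.geometry,
                years=[2010, 2013],
            )

    def test_region_partition_masks_other_counties(self):
        region, inputs, edi = self._setup()
        ids = region.county_ids
        out = sp.run_spatialization(
            edi,
            region.zone_grid,
            inputs.population_grid,
            region.counties.set_index("county")["population"],
            inputs.expenditure.set_index("county")["pcon"],
            region.geometry,
            regions={"left": ids[:2], "right": ids[2:]},
        )
        left = out[("left", 2010)]
        other = np.isin(region.zone_grid, ids[2:])
        assert (left[other] == region.geometry.nodata).all()

    def test_geometry_mismatch_raises(self):
        region, inputs, edi = self._setup()
        bad_geom = GridGeometry(rows=5, cols=5)
        with pytest.raises(ValueError, match="geometry"):
            sp.run_spatialization(
                edi,
                region.zone_grid,
                inputs.population_grid,
                region.counties.set_index("county")["population"],
                inputs.expenditure.set_index("county")["pcon"],
                bad_geom,
            )
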