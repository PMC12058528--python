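"""Annualization rules: interpolation, extrapolation, conservation, downscaling."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr
from hypothesis import given
from hypothesis import strategies as st

from ulex import demographics as demo
from ulex.synthetic import AGE_GROUPS


def le_table(values_by_country: dict) -> pd.DataFrame:
    rows = []
    for c, vals in values_by_country.items():
        if np.isscalar(vals):
            vals = [vals] * len(demo.LE_BLOCKS)
        for b, v in zip(demo.LE_BLOCKS, vals):
            rows.append((c, b, float(v)))
    return pd.DataFrame(rows, columns=["country", "block_start", "life_expectancy"])


class TestLifeExpectancy:
    def test_constant_blocks_give_constant_plus_five(self):
        le = demo.interp_life_expectancy(le_table({0: 60.0}))
        assert (le.loc[0] == 65.0).all()

    def test_midpoint_interpolation_by_hand(self):
        # blocks 70 (1950-1955) and 72 (1955-1960): midpoints 1952.5 / 1957.5,
        # so 1955 interpolates to 71, plus the 5-year birth adjustment
        vals = [70.0, 72.0] + [72.0] * (len(demo.LE_BLOCKS) - 2)
        le = demo.interp_life_expectancy(le_table({0: vals}), birth_years=(1950, 1960))
        assert le.loc[0, 1955] == pytest.approx((70 + 72) / 2 + 5)

    def test_constant_extension_before_first_midpoint(self):
        vals = [70.0] + [80.0] * (len(demo.LE_BLOCKS) - 1)
        le = demo.interp_life_expectancy(le_table({0: vals}), birth_years=(1950, 1960))
        assert le.loc[0, 1950] == pytest.approx(75.0)
        assert le.loc[0, 1951] == pytest.approx(75.0)

    def test_missing_block_is_an_error(self):
        tbl = le_table({0: 60.0})
        tbl = tbl[tbl.block_start != 1980]
        with pytest.raises(ValueError, match="1980"):
            demo.interp_life_expectancy(tbl)


class TestPopulationExtrapolation:
    @staticmethod
    def series(values, year0):
        vals = np.asarray(values, dtype=float)[:, None, None]
        return xr.DataArray(
            vals, dims=("time", "lat", "lon"),
            coords={"time": year0 + np.arange(len(values)), "lat": [0.0], "lon": [0.0]})

    def test_constant_is_a_fixed_point(self):
        p = self.series([1000.0] * 12, 2089)
        out = demo.extrapolate_population(p, 2113)
        assert (out.values == 1000.0).all()
        assert out.time.values.max() == 2113

    def test_trailing_mean_hand_values(self):
        p = self.series(np.arange(91, 101), 2091)
        out = demo.extrapolate_population(p, 2102)
        assert out.sel(time=2101).item() == pytest.approx(95.5)
        assert out.sel(time=2102).item() == pytest.approx(95.95)

    def test_too_short_history_is_an_error(self):
        p = self.series([1.0] * 5, 2096)
        with pytest.raises(ValueError, match="10"):
            demo.extrapolate_population(p, 2113)


def cohort_table(country_sizes: dict) -> pd.DataFrame:
    """country -> {year: {age_group: size}} or a callable(year, group)."""
    rows = []
    years = range(1950, 2101, 5)
    for c, spec in country_sizes.items():
        for y in years:
            for g in AGE_GROUPS:
                rows.append((c, y, g, float(spec(y, g))))
    return pd.DataFrame(rows, columns=["country", "year", "age_group", "size"])


class TestCohortSizes:
    def test_group_split_by_five(self):
        tbl = cohort_table({0: lambda y, g: 5e6})
        absolute, _ = demo.interp_cohort_sizes(tbl)
        for age in (0, 4, 97):
            assert absolute.sel(country=0, age=age, year=1960).item() == pytest.approx(1e6)
        assert absolute.sel(country=0, age=100, year=1960).item() == pytest.approx(5e6)

    def test_constant_table_constant_everywhere(self):
        tbl = cohort_table({0: lambda y, g: 1e6})
        absolute, shares = demo.interp_cohort_sizes(tbl)
        assert np.allclose(absolute.sel(age=3).values, 2e5)
        assert np.allclose(shares.sel(age=3).values, (1e6 / 5) / (20 * 1e6 + 1e6))

    def test_linear_extrapolation_hand_value(self):
        # one age class rising 100 -> 110 across 2095..2100 (group totals x5);
        # 2113 extrapolates to 110 + 13 * (110 - 100) / 5 = 136
        def spec(y, g):
            base = 500.0
            if g == "0-4":
                return 5 * (100.0 + (y - 2095) * 2.0) if y >= 2095 else 500.0
            return base
        tbl = cohort_table({0: spec})
        absolute, _ = demo.interp_cohort_sizes(tbl)
        assert absolute.sel(country=0, age=0, year=2113).item() == pytest.approx(136.0)

    def test_negative_extrapolation_clamped_to_zero(self, caplog):
        # the 0-4 group collapses 500 -> 250 -> 5 over 2090..2100, so the
        # annual slope at 2100 is steeply negative and extrapolation would
        # cross zero well before 2113
        def spec(y, g):
            if g == "0-4":
                return {2090: 500.0, 2095: 250.0, 2100: 5.0}.get(y, 500.0)
            return 500.0
        tbl = cohort_table({0: spec})
        with caplog.at_level("WARNING", logger="ulex"):
            absolute, _ = demo.interp_cohort_sizes(tbl)
        assert float(absolute.sel(country=0, age=0, year=2113)) == 0.0
        assert "clamped" in caplog.text

    def test_roundtrip_conservation_at_table_years(self, small_world):
        """Re-aggregating annual ages to 5-year groups reproduces the source."""
        _, demog, _ = small_world
        tbl = demog["cohort_sizes"]
        absolute, _ = demo.interp_cohort_sizes(tbl)
        pivot = tbl.pivot_table(index=["country", "age_group"], columns="year",
                                values="size")
        for year in (1960, 2000, 2100):
            for c in absolute.country.values:
                for lo in (0, 25, 95):
                    got = absolute.sel(
                        country=c, age=slice(lo, lo + 4), year=year).sum().item()
                    want = pivot.loc[(c, f"{lo}-{lo + 4}"), year]
                    assert got == pytest.approx(want, rel=1e-6)

    @given(v0=st.floats(1.0, 1e6), v1=st.floats(1.0, 1e6))
    def test_interpolation_stays_between_anchors(self, v0, v1):
        def spec(y, g):
            return v0 + (v1 - v0) * (y - 1950) / 150.0
        tbl = cohort_table({0: spec})
        absolute, _ = demo.interp_cohort_sizes(tbl)
        series = absolute.sel(country=0, age=50, year=slice(1960, 2100)).values
        lo, hi = min(v0, v1) / 5, max(v0, v1) / 5
        assert np.all(series >= lo - 1e-6 * hi) and np.all(series <= hi * (1 + 1e-9))


class TestGridCohortSizes:
    @staticmethod
    def grid(pop_vals, mask_vals, share0, years=(2020,), countries=None):
        nlat, nlon = np.asarray(mask_vals).shape
        coords = {"lat": 0.5 * np.arange(nlat), "lon": 0.5 * np.arange(nlon)}
        pop = xr.DataArray(
            np.broadcast_to(np.asarray(pop_vals, float), (len(years), nlat, nlon)),
            dims=("time", "lat", "lon"), coords={"time": list(years), **coords})
        mask = xr.DataArray(np.asarray(mask_vals, dtype=np.int32),
                            dims=("lat", "lon"), coords=coords)
        if countries is None:
            countries = sorted({int(c) for c in np.unique(mask_vals) if c >= 0})
        shares = xr.DataArray(
            np.full((len(countries), 1, len(years)), share0),
            dims=("country", "age", "year"),
            coords={"country": countries, "age": [0], "year": list(years)})
        return pop, shares, mask

    def test_product_arithmetic(self):
        pop, shares, mask = self.grid([[10_000.0]], [[0]], 0.012)
        b = demo.cohort_size_at_grid(pop, shares, mask, np.array([2020]))
        assert b.item() == pytest.approx(120.0)

    def test_zero_share_gives_zero(self):
        pop, shares, mask = self.grid([[10_000.0]], [[0]], 0.0)
        b = demo.cohort_size_at_grid(pop, shares, mask, np.array([2020]))
        assert b.item() == 0.0

    def test_within_country_homogeneity(self):
        pop, shares, mask = self.grid([[1000.0, 3000.0]], [[0, 0]], 0.01)
        b = demo.cohort_size_at_grid(pop, shares, mask, np.array([2020])).values.ravel()
        assert b[1] == pytest.approx(3 * b[0])

    def test_unassigned_populated_land_cell_is_an_error(self):
        pop, shares, mask = self.grid([[1000.0, 3000.0]], [[0, 7]], 0.01,
                                      countries=[0])
        with pytest.raises(ValueError, match="country"):
            demo.cohort_size_at_grid(pop, shares, mask, np.array([2020]))

    def test_country_aggregate_matches_age0_total(self, small_world, small_demography):
        _, demog, _ = small_world
        cd = small_demography
        pop = demo.extrapolate_population(demog["population"])
        b = demo.cohort_size_at_grid(pop, cd.shares, demog["mask"], np.array([2000]))
        m = demog["mask"].values
        for c in cd.le.index:
            got = float(b.values[0][m == c].sum())
            want = (float(pop.sel(time=2000).values[m == c].sum())
                    * cd.age0_share(c, 2000))
            assert got == pytest.approx(want, rel=1e-6)


def test_final_analysis_year_within_bound(small_demography):
    assert demo.final_analysis_year(small_demography.le) <= 2113
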