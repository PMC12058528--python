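"""Annualized, grid-scale demography from 5-year country tables.

Converts 5-year life-expectancy blocks and 5-year cohort-size tables into
annual birth-cohort life expectancies and single-year age-class sizes, then
downscales birth-cohort sizes to the grid by assuming cohort structure and
life expectancy are spatially homogeneous within each country.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .util import get_logger

log = get_logger("demographics")

LE_BLOCKS = tuple(range(1950, 2020, 5))  # 1950-1955 .. 2015-2020
DEFAULT_BIRTH_YEARS = (1960, 2020)
FINAL_YEAR = 2113


@dataclass
class CountryDemography:
    """Annualized country demography.

    ``le``: life expectancy at birth per (country, birth year), the +5
    adjustment applied.  ``cohort_sizes``: absolute single-year age-class
    sizes (country, age 0..100, year).  ``shares``: the same relative to the
    all-age total of the (country, year).
    """

    le: pd.DataFrame                 # index country, columns birth years
    cohort_sizes: xr.DataArray       # (country, age, year)
    shares: xr.DataArray             # (country, age, year)
    raw_le_blocks: pd.DataFrame
    raw_cohort_table: pd.DataFrame

    def le_of(self, country: int, birth_year: int) -> float:
        return float(self.le.loc[country, birth_year])

    def age0_share(self, country: int, year: int) -> float:
        return float(self.shares.sel(country=country, age=0, year=year))


def interp_life_expectancy(
    blocks: pd.DataFrame,
    birth_years: tuple[int, int] = DEFAULT_BIRTH_YEARS,
) -> pd.DataFrame:
    """Annual life expectancy at birth from 5-year blocks of LE of 5-year-olds.

    Block values are taken as representative of the block midpoint (1950-1955
    -> 1952.5) and linearly interpolated between midpoints; outside the
    outermost midpoints values are held constant.  5 years are added after
    interpolation so the result measures expectancy since birth.

    ``blocks`` needs columns country, block_start, life_expectancy covering
    every block 1950 .. 2015 for every country.
    """
    required = {"country", "block_start", "life_expectancy"}
    if not required.issubset(blocks.columns):
        raise ValueError(f"life-expectancy table must have columns {sorted(required)}")
    years = np.arange(birth_years[0], birth_years[1] + 1)
    midpoints = np.array(LE_BLOCKS, dtype=float) + 2.5
    out = {}
    for c, grp in blocks.groupby("country"):
        grp = grp.set_index("block_start")["life_expectancy"]
        missing = [b for b in LE_BLOCKS if b not in grp.index]
        if missing:
            raise ValueError(
                f"country {c}: missing life-expectancy block(s) starting {missing}"
            )
        vals = grp.loc[list(LE_BLOCKS)].to_numpy(dtype=float)
        out[c] = np.interp(years.astype(float), midpoints, vals) + 5.0
    le = pd.DataFrame(out, index=pd.Index(years, name="birth_year")).T
    le.index.name = "country"
    return le


def extrapolate_population(
    population: xr.DataArray, to_year: int = FINAL_YEAR
) -> xr.DataArray:
    """Extend a gridded annual population beyond its last year.

    Each new year is the mean of the preceding 10 years, with previously
    extrapolated years entering subsequent means (so 2101 is the mean of
    2091-2100, 2102 the mean of 2092-2101, ...).
    """
    years = population.time.values.astype(int)
    last = int(years.max())
    if to_year <= last:
        return population
    if years.size < 10:
        raise ValueError(
            f"need at least 10 trailing years to extrapolate, have {years.size}"
        )
    vals = population.transpose("time", ...).values
    buf = list(vals[-10:])
    new = []
    for _ in range(last + 1, to_year + 1):
        nxt = np.mean(buf[-10:], axis=0)
        buf.append(nxt)
        new.append(nxt)
    ext = xr.DataArray(
        np.stack(new), dims=population.transpose("time", ...).dims,
        coords={"time": np.arange(last + 1, to_year + 1),
                **{d: population.coords[d] for d in population.dims if d != "time"}},
        name=population.name,
    )
    return xr.concat([population.transpose("time", ...), ext], dim="time")


def _parse_age_group(g: str) -> tuple[int, int]:
    if g.endswith("+"):
        a = int(g[:-1])
        return a, a
    m = re.fullmatch(r"(\d+)-(\d+)", g)
    if not m:
        raise ValueError(f"unparseable age group {g!r}")
    return int(m.group(1)), int(m.group(2))


def interp_cohort_sizes(
    table: pd.DataFrame,
    years: tuple[int, int] = (1960, FINAL_YEAR),
) -> tuple[xr.DataArray, xr.DataArray]:
    """Annual single-year age-class sizes and shares from a 5-year table.

    Each 5-year age-group total is split as total/5 per single-year age (the
    open-ended 100+ group maps to the single age 100), interpolated linearly
    across table years, and extended past the last table year by linear
    extrapolation from the last two annual values; negative extrapolations
    are clamped to zero with a warning.  Shares are taken against the
    interpolated all-age total.

    ``table`` needs columns country, year (1950:5:2100), age_group, size.
    Returns ``(absolute, shares)`` with dims (country, age, year).
    """
    required = {"country", "year", "age_group", "size"}
    if not required.issubset(table.columns):
        raise ValueError(f"cohort table must have columns {sorted(required)}")
    table_years = np.arange(1950, 2101, 5)
    countries = np.sort(table["country"].unique())
    ages = np.arange(0, 101)
    out_years = np.arange(years[0], years[1] + 1)

    pivot = table.pivot_table(
        index=["country", "age_group"], columns="year", values="size", aggfunc="sum"
    )
    missing_years = [y for y in table_years if y not in pivot.columns]
    if missing_years:
        raise ValueError(f"cohort table missing year(s) {missing_years}")

    abs_sizes = np.zeros((countries.size, ages.size, out_years.size))
    clamped = 0
    for ci, c in enumerate(countries):
        sub = pivot.loc[c]
        annual_ages = np.full((ages.size, table_years.size), np.nan)
        for g, row in sub.iterrows():
            lo, hi = _parse_age_group(str(g))
            span = hi - lo + 1
            for a in range(lo, min(hi, 100) + 1):
                annual_ages[a] = row.loc[table_years].to_numpy(dtype=float) / span
        if np.isnan(annual_ages).any():
            bad = ages[np.isnan(annual_ages).any(axis=1)]
            raise ValueError(f"country {c}: age(s) {bad.tolist()} not covered by any group")
        # linear interpolation within table span, then linear extrapolation
        interp_years = out_years[out_years <= table_years[-1]]
        vals = np.empty((ages.size, out_years.size))
        for ai in range(ages.size):
            vals[ai, : interp_years.size] = np.interp(
                interp_years.astype(float), table_years.astype(float), annual_ages[ai]
            )
        n_ext = out_years.size - interp_years.size
        if n_ext > 0:
            v_last = vals[:, interp_years.size - 1]
            v_prev = vals[:, interp_years.size - 2]
            slope = v_last - v_prev
            steps = np.arange(1, n_ext + 1)
            ext = v_last[:, None] + slope[:, None] * steps[None, :]
            clamped += int((ext < 0).sum())
            vals[:, interp_years.size:] = np.clip(ext, 0.0, None)
        abs_sizes[ci] = vals
    if clamped:
        log.warning("clamped %d negative extrapolated cohort sizes to 0", clamped)

    coords = {"country": countries, "age": ages, "year": out_years}
    absolute = xr.DataArray(abs_sizes, dims=("country", "age", "year"),
                            coords=coords, name="cohort_size")
    totals = absolute.sum("age")
    shares = (absolute / totals.where(totals > 0)).fillna(0.0).rename("cohort_share")
    return absolute, shares


def build_country_demography(
    le_blocks: pd.DataFrame,
    cohort_table: pd.DataFrame,
    birth_years: tuple[int, int] = DEFAULT_BIRTH_YEARS,
) -> CountryDemography:
    le = interp_life_expectancy(le_blocks, birth_years)
    absolute, shares = interp_cohort_sizes(cohort_table)
    missing = set(le.index) - set(absolute.country.values.tolist())
    if missing:
        raise ValueError(f"countries {sorted(missing)} missing from cohort table")
    fy = final_analysis_year(le)
    if fy > FINAL_YEAR:
        log.warning(
            "longest lifetime ends in %d, past the final analysis year %d; "
            "exposures will be truncated", fy, FINAL_YEAR,
        )
    return CountryDemography(le, absolute, shares, le_blocks, cohort_table)


def final_analysis_year(le: pd.DataFrame) -> int:
    """Last calendar year touched by any cohort: max over countries of
    birth-year + life expectancy, rounded up."""
    last_by = int(max(le.columns))
    return int(math.ceil(float(le[last_by].max()) + last_by))


def cohort_size_at_grid(
    population: xr.DataArray,
    shares: xr.DataArray,
    mask: xr.DataArray,
    birth_years: np.ndarray | None = None,
) -> xr.DataArray:
    """Gridded birth-cohort sizes B(x, b) = P(x, b) * age-0 share of the
    cell's country in year b.

    Cells with mask < 0 (sea / unassigned) get zero; an unassigned land cell
    carrying population is a consistency error.
    """
    if birth_years is None:
        birth_years = np.arange(DEFAULT_BIRTH_YEARS[0], DEFAULT_BIRTH_YEARS[1] + 1)
    birth_years = np.asarray(birth_years, dtype=int)
    m = mask.values
    known = np.asarray(shares.country.values)
    land = m >= 0
    unknown = land & ~np.isin(m, known)
    if unknown.any():
        pop_there = population.isel(time=0).values[unknown]
        if np.any(pop_there > 0):
            ij = np.argwhere(unknown)[0]
            raise ValueError(
                f"cell (lat={ij[0]}, lon={ij[1]}) has population but its country "
                f"{m[tuple(ij)]} is absent from the cohort table"
            )
    share0 = shares.sel(age=0)  # (country, year)
    out = np.zeros((birth_years.size, *m.shape))
    pop = population.sel(time=birth_years).transpose("time", "lat", "lon").values
    for c in known:
        sel = m == c
        if not sel.any():
            continue
        s = share0.sel(country=c, year=birth_years).values  # (birth_year,)
        out[:, sel] = pop[:, sel] * s[:, None]
    return xr.DataArray(
        out, dims=("birth_year", "lat", "lon"),
        coords={"birth_year": birth_years, "lat": mask.lat, "lon": mask.lon},
        name="birth_cohort_size",
    )
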