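"""Socioeconomic stratification of ULE by population-weighted quantiles.

Birth cohorts are ranked on a gridded vulnerability indicator — a 0-100
deprivation index, or lifetime-mean GDP per capita — and cut into five bins
of nearly equal cohort population.  The bottom and top 20% are then compared
for their incidence of unprecedented lifetime exposure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .emergence import SignificanceResult, ensemble_significance
from .util import get_logger, year_weights

log = get_logger("vulnerability")


def extend_series_copy_forward(field: xr.DataArray, to_year: int) -> xr.DataArray:
    """Extend an annual gridded series by repeating its final year."""
    years = field.time.values.astype(int)
    last = int(years.max())
    if to_year <= last:
        return field
    fld = field.transpose("time", ...)
    tail = np.repeat(fld.isel(time=-1).values[None, ...], to_year - last, axis=0)
    ext = xr.DataArray(
        tail, dims=fld.dims,
        coords={"time": np.arange(last + 1, to_year + 1),
                **{d: field.coords[d] for d in field.dims if d != "time"}},
        name=field.name,
    )
    return xr.concat([fld, ext], dim="time")


def lifetime_mean_gdp(
    gdp: xr.DataArray,
    population: xr.DataArray,
    le: pd.DataFrame,
    mask: xr.DataArray,
    birth_year: int,
) -> xr.DataArray:
    """Lifetime-mean GDP per capita per cell for one birth cohort.

    The GDP series is first extended by copying its final year so every
    lifetime is covered; the per-cell mean of GDP(x,t)/P(x,t) over the
    cohort's lifetime weights the death year by the fraction lived.  Cells
    with zero population but positive GDP are flagged and excluded (NaN).
    """
    end = int(max(
        birth_year + int(np.ceil(float(le[birth_year].max()))),
        population.time.values.max(),
    ))
    gdp = extend_series_copy_forward(gdp, end)
    population = extend_series_copy_forward(population, end)
    m = mask.values
    gvals = gdp.transpose("time", "lat", "lon").values
    pvals = population.transpose("time", "lat", "lon").values
    times = gdp.time.values.astype(int)
    tindex = {int(t): i for i, t in enumerate(times)}
    out = np.full(m.shape, np.nan)
    bad = 0
    for c in le.index:
        sel = m == c
        if not sel.any():
            continue
        years, weights = year_weights(birth_year, float(le.loc[c, birth_year]))
        idx = np.fromiter((tindex[int(y)] for y in years), dtype=int)
        g = gvals[idx][:, sel]
        p = pvals[idx][:, sel]
        zero_pop = (p <= 0) & (g > 0)
        if zero_pop.any():
            bad += int(zero_pop.any(axis=0).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            pc = np.where(p > 0, g / np.where(p > 0, p, 1.0), np.nan)
        out[sel] = (pc * weights[:, None]).sum(axis=0) / weights.sum()
        out_sel = out[sel]
        out_sel[zero_pop.any(axis=0)] = np.nan
        out[sel] = out_sel
    if bad:
        log.warning("%d cell(s) with zero population but positive GDP excluded", bad)
    return xr.DataArray(
        out, dims=("lat", "lon"), coords={"lat": mask.lat, "lon": mask.lon},
        name="lifetime_mean_gdp_pc", attrs={"birth_year": birth_year},
    )


@dataclass
class QuantileBins:
    """Population-weighted quantile bins of a vulnerability indicator."""

    bin_map: xr.DataArray            # int bin id 1..k; 0 = no cohort population
    populations: pd.Series           # cohort population per bin
    k: int
    birth_year: int

    def stratum_mask(self, b: int) -> xr.DataArray:
        return (self.bin_map == b).rename(f"stratum_{b}")


def population_weighted_bins(
    indicator: xr.DataArray,
    cohort_size: xr.DataArray,
    k: int = 5,
    birth_year: int | None = None,
) -> QuantileBins:
    """Cut cells, ranked by indicator, into ``k`` bins of nearly equal population.

    Cells are sorted by indicator value (ties broken by stable cell index)
    and the cumulative cohort population is cut at ``i/k`` of the total; the
    straddling cell closes the lower bin, so every cell is wholly assigned
    and bins are only as equal as the grid-scale population granularity
    allows.  Rank-based: any strictly monotone transform of the indicator
    yields identical bins.
    """
    ind = indicator.values.ravel()
    pop = cohort_size.values.ravel()
    eligible = np.isfinite(ind) & (pop > 0)
    n_elig = int(eligible.sum())
    if n_elig == 0:
        raise ValueError("no cell carries cohort population")
    if k > n_elig:
        raise ValueError(f"cannot form {k} bins from {n_elig} populated cells")
    order = np.argsort(ind[eligible], kind="stable")
    cells = np.flatnonzero(eligible)[order]
    cum = np.cumsum(pop[cells])
    total = cum[-1]
    bins = np.zeros(ind.size, dtype=np.int32)
    start = 0
    for i in range(1, k + 1):
        target = total * i / k
        stop = int(np.searchsorted(cum, target - 1e-9 * total)) + 1
        stop = min(stop, cells.size)
        bins[cells[start:stop]] = i
        start = stop
    pops = pd.Series(
        {i: float(pop[bins.reshape(-1) == i].sum()) for i in range(1, k + 1)},
        name="population",
    )
    bin_map = xr.DataArray(
        bins.reshape(indicator.shape), dims=indicator.dims,
        coords=indicator.coords, name="vulnerability_bin",
    )
    by = birth_year if birth_year is not None else int(cohort_size.attrs.get("birth_year", -1))
    return QuantileBins(bin_map, pops, k, by)


@dataclass
class StrataComparison:
    """ULE incidence in the bottom and top vulnerability strata of one cohort."""

    birth_year: int
    strata: tuple[int, int]
    totals: dict[int, float]                  # stratum -> cohort population
    per_run_fractions: pd.DataFrame           # columns run, stratum, fraction
    mean_fraction: dict[int, float]
    sd_fraction: dict[int, float]
    significance: SignificanceResult


def strata_ule(
    emerged_by_run: dict[str, xr.DataArray],
    bins: QuantileBins,
    cohort_size: xr.DataArray,
    strata: tuple[int, int] | None = None,
    alpha: float = 0.05,
) -> StrataComparison:
    """Compare emerged cohort fractions between two vulnerability strata.

    ``emerged_by_run``: per ensemble member, the boolean emergence grid of
    one birth cohort.  Fractions are per-stratum cohort population emerged;
    the two strata (default bottom and top quantile bins) are compared with
    a two-sided ensemble test at ``alpha``.
    """
    if strata is None:
        strata = (1, bins.k)
    totals = {}
    masks = {}
    for s in strata:
        msk = bins.stratum_mask(s)
        tot = float(cohort_size.where(msk, 0.0).sum())
        if tot <= 0:
            raise ValueError(f"stratum {s} holds no cohort population")
        totals[s] = tot
        masks[s] = msk
    rows = []
    for rid, emerged in sorted(emerged_by_run.items()):
        for s in strata:
            count = float((emerged * cohort_size).where(masks[s], 0.0).sum())
            rows.append((rid, s, count / totals[s]))
    per_run = pd.DataFrame(rows, columns=["run", "stratum", "fraction"])
    mean_f = {s: float(per_run.loc[per_run.stratum == s, "fraction"].mean()) for s in strata}
    sd_f = {s: float(per_run.loc[per_run.stratum == s, "fraction"].std(ddof=1)) for s in strata}
    sig = ensemble_significance(
        per_run.loc[per_run.stratum == strata[0], "fraction"].to_numpy(),
        per_run.loc[per_run.stratum == strata[1], "fraction"].to_numpy(),
        alpha=alpha,
    )
    return StrataComparison(bins.birth_year, strata, totals, per_run, mean_f, sd_f, sig)


def strata_table(comparisons: list[StrataComparison]) -> pd.DataFrame:
    """Flat summary table (birth year, stratum, total, emerged mean, SD, significance)."""
    rows = []
    for c in comparisons:
        for s in c.strata:
            rows.append({
                "birth_year": c.birth_year,
                "stratum": s,
                "cohort_total": c.totals[s],
                "fraction_mean": c.mean_fraction[s],
                "fraction_sd": c.sd_fraction[s],
                "significant": c.significance.significant,
                "pvalue": c.significance.pvalue,
                "test": c.significance.method,
            })
    return pd.DataFrame(rows)
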