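"""Cumulative lifetime exposure from annual exposure-fraction fields.

All people in a 0.5-degree cell count as exposed in a year when the hazard
occurs there, so a cohort's lifetime exposure is the sum of the cell's annual
exposed-area fractions over its lifetime, with the death year weighted by the
fraction of that year lived.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import xarray as xr

from .util import get_logger, nearest_rank_percentile, year_weights

log = get_logger("lifetime")


def occurrence_from_indicator(
    indicator: xr.DataArray,
    control: xr.DataArray,
    percentile: float = 99.0,
) -> xr.DataArray:
    """Binary event occurrence from a localized pre-industrial threshold.

    Per cell, the threshold is the nearest-rank ``percentile`` of the control
    indicator; an event occurs in a year when the indicator lies strictly
    above it.  This is the generic form of the hazard definitions that
    compare an annual indicator (heat index, soil moisture, discharge, yield)
    against its distribution in a stationary pre-industrial climate.
    """
    n = control.sizes["time"]
    need = int(math.ceil(1.0 / (1.0 - percentile / 100.0)))
    if n < need:
        raise ValueError(
            f"control of {n} years is too short for the {percentile} percentile "
            f"(need at least {need})"
        )
    ctl = control.transpose("time", ...).values
    thr = nearest_rank_percentile(ctl, percentile, axis=0)
    thr_da = xr.DataArray(
        thr, dims=[d for d in control.dims if d != "time"],
        coords={d: control.coords[d] for d in control.dims if d != "time"},
    )
    return (indicator > thr_da).astype(np.int8).rename("occurrence")


def cumulative_lifetime_exposure(
    field: xr.DataArray, birth_year: int, life_expectancy: float
) -> xr.DataArray:
    """Lifetime exposure E(x) of one birth cohort under one exposure field.

    ``E = sum_{k=0}^{floor(L)-1} f(x, b+k) + (L - floor(L)) * f(x, b+floor(L))``.
    If the field ends before the lifetime does, the sum is truncated with a
    warning.
    """
    years, weights = year_weights(birth_year, life_expectancy)
    avail = field.time.values.astype(int)
    have = np.isin(years, avail)
    if not have.all():
        log.warning(
            "field ends in %d; truncating lifetime of birth year %d (L=%.2f) "
            "missing %d year(s)", int(avail.max()), birth_year, life_expectancy,
            int((~have).sum()),
        )
        years, weights = years[have], weights[have]
    sub = field.sel(time=years).transpose("time", ...)
    vals = (sub.values * weights[(slice(None),) + (None,) * (sub.ndim - 1)]).sum(axis=0)
    dims = [d for d in sub.dims if d != "time"]
    return xr.DataArray(
        vals, dims=dims, coords={d: field.coords[d] for d in dims},
        name="lifetime_exposure",
        attrs={"birth_year": birth_year, "life_expectancy": life_expectancy,
               **field.attrs},
    )


def exposure_trajectory(
    field: xr.DataArray, birth_year: int, life_expectancy: float
) -> xr.DataArray:
    """Running cumulative exposure since birth, one entry per age.

    The final element equals :func:`cumulative_lifetime_exposure`.
    """
    years, weights = year_weights(birth_year, life_expectancy)
    avail = field.time.values.astype(int)
    have = np.isin(years, avail)
    if not have.all():
        log.warning(
            "field ends in %d; truncating trajectory of birth year %d",
            int(avail.max()), birth_year,
        )
        years, weights = years[have], weights[have]
    sub = field.sel(time=years).transpose("time", ...)
    vals = np.cumsum(
        sub.values * weights[(slice(None),) + (None,) * (sub.ndim - 1)], axis=0
    )
    coords = {d: field.coords[d] for d in sub.dims if d != "time"}
    coords["age"] = np.arange(years.size)
    out = xr.DataArray(
        vals, dims=("age",) + tuple(d for d in sub.dims if d != "time"),
        coords=coords, name="cumulative_exposure",
        attrs={"birth_year": birth_year, "life_expectancy": life_expectancy},
    )
    return out


def lifetime_exposure_grid(
    field: xr.DataArray,
    mask: xr.DataArray,
    le: pd.DataFrame,
    birth_years: np.ndarray | None = None,
) -> xr.DataArray:
    """E(x, b) for all birth years, with country-specific life expectancy.

    ``le``: annual life expectancy table (index country, columns birth
    years).  Cells outside any country get zero.
    """
    if birth_years is None:
        birth_years = np.asarray(le.columns, dtype=int)
    birth_years = np.asarray(birth_years, dtype=int)
    m = mask.values
    fld = field.transpose("time", "lat", "lon")
    fvals = fld.values
    times = fld.time.values.astype(int)
    tindex = {int(t): i for i, t in enumerate(times)}
    out = np.zeros((birth_years.size, *m.shape))
    for bi, b in enumerate(birth_years):
        for c in le.index:
            sel = m == c
            if not sel.any():
                continue
            years, weights = year_weights(int(b), float(le.loc[c, b]))
            have = np.isin(years, times)
            if not have.all():
                years, weights = years[have], weights[have]
            idx = np.fromiter((tindex[int(y)] for y in years), dtype=int)
            out[bi, sel] = (fvals[idx][:, sel] * weights[:, None]).sum(axis=0)
    return xr.DataArray(
        out, dims=("birth_year", "lat", "lon"),
        coords={"birth_year": birth_years, "lat": mask.lat, "lon": mask.lon},
        name="lifetime_exposure", attrs=dict(field.attrs),
    )


def multi_model_mean(grids: list[xr.DataArray]) -> xr.DataArray:
    """Mean lifetime exposure across ensemble members (runs)."""
    if not grids:
        raise ValueError("no grids to average")
    return xr.concat(grids, dim="run").mean("run").rename("lifetime_exposure_mean")
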