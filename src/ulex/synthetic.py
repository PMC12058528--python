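"""Synthetic input worlds with analytic ground truth.

Generates everything the pipeline consumes — gridded annual exposure-fraction
ensembles driven by global mean temperature (GMT), long stationary
pre-industrial controls, country demography tables, gridded population, and
vulnerability surfaces — from a single seeded configuration.

The hazard model is deliberately simple so that the truth is computable in
closed form: each grid cell experiences an event in year ``t`` as a Bernoulli
trial with probability ``p(x, t) = clamp(p0(x) + beta(x) * W(t), 0, 1)``,
where ``W`` is the (noisy) GMT anomaly of the forcing run, and an event
exposes a fixed area fraction ``a(x)`` of the cell.  Lifetime exposure is then
a scaled Poisson-binomial sum whose tail — and hence the true probability of
unprecedented lifetime exposure per cell, cohort and pathway — has an exact
dynamic-programming evaluation (:func:`true_cohort_fraction`).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats

from .util import child_rng, get_logger, year_weights

log = get_logger("synthetic")

#: pre-industrial control period start used to label control years
CONTROL_YEAR0 = 1666

#: nominal end-of-century warming (degC vs 1850-1900) per forcing scenario
SCENARIO_END_GMT = {"picontrol": 0.0, "rcp26": 1.9, "rcp60": 2.9, "rcp85": 4.3}

AGE_GROUPS = [f"{a}-{a + 4}" for a in range(0, 100, 5)] + ["100+"]


@dataclass(frozen=True)
class RunSpec:
    """One ensemble member: climate model x impact model x forcing scenario."""

    gcm: str
    impact_model: str
    scenario: str

    @property
    def run_id(self) -> str:
        return f"{self.gcm}_{self.impact_model}_{self.scenario}"


def default_runs(n: int = 4) -> list[RunSpec]:
    gcms = ["gcm-a", "gcm-b", "gcm-c", "gcm-d", "gcm-e", "gcm-f"]
    scenarios = ["rcp26", "rcp60", "rcp85", "rcp60", "rcp85", "rcp26"]
    return [RunSpec(gcms[i % 6], "impact-1", scenarios[i % 6]) for i in range(n)]


@dataclass
class SynthConfig:
    """Configuration of a synthetic world.

    Hazard parameters are drawn per cell from the stated uniform ranges; pass
    a degenerate range ``(c, c)`` for spatially constant values.
    """

    n_lat: int = 10
    n_lon: int = 10
    cell_deg: float = 0.5
    n_countries: int = 4
    year_start: int = 1861          # historical period start
    year_end: int = 2099            # future period end
    control_years: int = 639        # per-run stationary control length
    runs: list[RunSpec] = field(default_factory=default_runs)
    hazard: str = "heatwave"
    # hazard model: p(x,t) = clamp(p0 + beta * W, 0, 1); exposed fraction a
    p0_range: tuple[float, float] = (0.004, 0.02)
    beta_range: tuple[float, float] = (0.005, 0.03)   # per degC
    exposed_fraction_range: tuple[float, float] = (1.0, 1.0)
    # GMT forcing
    gmt_noise_sd: float = 0.08      # interannual variability, degC
    gcm_offset_sd: float = 0.15     # per-GCM spread of end-of-century warming
    # demographics
    le_1950_range: tuple[float, float] = (55.0, 70.0)
    le_2020_range: tuple[float, float] = (68.0, 82.0)
    country_pop_range: tuple[float, float] = (5e6, 5e7)   # persons, 1950
    pop_growth_range: tuple[float, float] = (0.002, 0.010)  # per year
    # vulnerability
    deprivation_gdp_rank_corr: float = -0.7
    gdp_pc_median: float = 1e4
    birth_years: tuple[int, int] = (1960, 2020)
    master_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not 239 <= self.control_years <= 639:
            raise ValueError(
                f"control length must lie in [239, 639] years, got {self.control_years}"
            )
        for name, (lo, hi) in [("p0", self.p0_range), ("beta", self.beta_range),
                               ("exposed_fraction", self.exposed_fraction_range)]:
            if lo > hi:
                raise ValueError(f"{name}_range is decreasing: {(lo, hi)}")
        if not 0.0 <= self.p0_range[0] <= self.p0_range[1] <= 1.0:
            raise ValueError(f"baseline probability p0 outside [0, 1]: {self.p0_range}")
        if self.beta_range[0] < 0:
            raise ValueError(f"GMT sensitivity beta must be >= 0: {self.beta_range}")
        if not 0.0 < self.exposed_fraction_range[0] <= self.exposed_fraction_range[1] <= 1.0:
            raise ValueError(
                f"exposed fraction must lie in (0, 1]: {self.exposed_fraction_range}"
            )
        if not -1.0 <= self.deprivation_gdp_rank_corr <= 1.0:
            raise ValueError("deprivation/GDP rank correlation outside [-1, 1]")
        if self.n_countries < 1:
            raise ValueError("need at least one country")
        if self.n_countries > self.n_lat * self.n_lon:
            raise ValueError("more countries than grid cells")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_end + 1)

    @property
    def lat(self) -> np.ndarray:
        return np.arange(self.n_lat) * self.cell_deg

    @property
    def lon(self) -> np.ndarray:
        return np.arange(self.n_lon) * self.cell_deg


# ---------------------------------------------------------------------------
# grid geometry and per-cell hazard parameters
# ---------------------------------------------------------------------------

def country_mask(cfg: SynthConfig) -> xr.DataArray:
    """Integer country id per cell (contiguous blocks in scan order); -1 = sea."""
    n = cfg.n_lat * cfg.n_lon
    ids = np.minimum(np.arange(n) * cfg.n_countries // n, cfg.n_countries - 1)
    return xr.DataArray(
        ids.reshape(cfg.n_lat, cfg.n_lon).astype(np.int32),
        dims=("lat", "lon"), coords={"lat": cfg.lat, "lon": cfg.lon}, name="country",
    )


def hazard_parameters(cfg: SynthConfig) -> dict[str, xr.DataArray]:
    """Per-cell (p0, beta, a) drawn from the configured ranges."""
    rng = child_rng(cfg.master_seed, "hazard-params")
    shape = (cfg.n_lat, cfg.n_lon)
    coords = {"lat": cfg.lat, "lon": cfg.lon}

    def draw(lo: float, hi: float, name: str) -> xr.DataArray:
        vals = rng.uniform(lo, hi, size=shape) if hi > lo else np.full(shape, lo)
        return xr.DataArray(vals, dims=("lat", "lon"), coords=coords, name=name)

    return {
        "p0": draw(*cfg.p0_range, "p0"),
        "beta": draw(*cfg.beta_range, "beta"),
        "a": draw(*cfg.exposed_fraction_range, "exposed_fraction"),
    }


# ---------------------------------------------------------------------------
# GMT forcing
# ---------------------------------------------------------------------------

def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def warming_curve(years: np.ndarray, end_level: float) -> np.ndarray:
    """Deterministic anomaly curve: shared history, smooth ramp to 2100, flat after.

    History rises quadratically from 0 in 1880 to 1.2 degC in 2020 (all curves
    share it); from 2020 the curve relaxes monotonically to ``end_level`` at
    2100 with zero slope at both ends, which keeps early-decade overshoot of
    low pathways over high ones minimal.
    """
    years = np.asarray(years, dtype=float)
    hist_2020 = 1.2
    w = np.where(
        years <= 2020,
        hist_2020 * np.clip((years - 1880.0) / 140.0, 0.0, None) ** 2,
        hist_2020 + (end_level - hist_2020) * _smoothstep((years - 2020.0) / 80.0),
    )
    return w


def gen_gmt_anchors(
    cfg: SynthConfig,
    levels: tuple[float, ...] = (1.5, 2.5, 3.5),
    year_range: tuple[int, int] = (1960, 2113),
) -> pd.DataFrame:
    """Anchor GMT trajectories reaching the given end-of-century warming levels.

    Returns a DataFrame indexed by year with one column per anchor level.
    Curves are deterministic, end at their nominal level in 2100 and are
    pointwise non-decreasing in the anchor level.
    """
    lv = np.asarray(levels, dtype=float)
    if np.any(np.diff(lv) <= 0):
        raise ValueError(f"anchor levels must be strictly ascending, got {levels}")
    years = np.arange(year_range[0], year_range[1] + 1)
    return pd.DataFrame(
        {float(l): warming_curve(years, float(l)) for l in lv},
        index=pd.Index(years, name="year"),
    )


def run_gmt_series(cfg: SynthConfig, run: RunSpec) -> pd.Series:
    """Noisy annual GMT anomaly of one forcing run over its simulation years."""
    rng = child_rng(cfg.master_seed, "gmt", run.run_id)
    years = cfg.years
    if run.scenario == "picontrol":
        return pd.Series(0.0, index=pd.Index(years, name="year"), name=run.run_id)
    end = SCENARIO_END_GMT[run.scenario] + rng.normal(0.0, cfg.gcm_offset_sd)
    w = warming_curve(years, end) + rng.normal(0.0, cfg.gmt_noise_sd, size=years.size)
    return pd.Series(w, index=pd.Index(years, name="year"), name=run.run_id)


# ---------------------------------------------------------------------------
# exposure ensemble
# ---------------------------------------------------------------------------

@dataclass
class SyntheticEnsemble:
    """One generated world: exposure fields, controls, GMTs and true parameters."""

    cfg: SynthConfig
    fields: dict[str, xr.DataArray]      # run_id -> (time, lat, lon) exposed fraction
    controls: dict[str, xr.DataArray]    # run_id -> stationary control series
    gmt: dict[str, pd.Series]            # run_id -> annual GMT anomaly
    params: dict[str, xr.DataArray]      # true p0, beta, a
    mask: xr.DataArray

    @property
    def run_ids(self) -> list[str]:
        return list(self.fields)


def true_occurrence_probability(
    params: dict[str, xr.DataArray], w: float | np.ndarray
) -> xr.DataArray:
    """clamp(p0 + beta * W, 0, 1) — the generator's event probability."""
    w = xr.DataArray(np.asarray(w), dims=("time",)) if np.ndim(w) else float(w)
    return (params["p0"] + params["beta"] * w).clip(0.0, 1.0)


def gen_exposure_ensemble(cfg: SynthConfig) -> SyntheticEnsemble:
    """Generate per-run exposure fields, one stationary control per run, and GMTs."""
    params = hazard_parameters(cfg)
    mask = country_mask(cfg)
    p0 = params["p0"].values
    beta = params["beta"].values
    a = params["a"].values
    coords = {"lat": cfg.lat, "lon": cfg.lon}

    fields: dict[str, xr.DataArray] = {}
    controls: dict[str, xr.DataArray] = {}
    gmt: dict[str, pd.Series] = {}
    for run in cfg.runs:
        rid = run.run_id
        w = run_gmt_series(cfg, run)
        gmt[rid] = w
        rng = child_rng(cfg.master_seed, "exposure", rid)
        p = np.clip(p0[None, :, :] + beta[None, :, :] * w.values[:, None, None], 0.0, 1.0)
        occ = rng.random(p.shape) < p
        fields[rid] = xr.DataArray(
            occ * a[None, :, :], dims=("time", "lat", "lon"),
            coords={"time": w.index.values, **coords}, name="exposure",
            attrs={"hazard": cfg.hazard, "run": rid, "scenario": run.scenario},
        )
        rng_c = child_rng(cfg.master_seed, "control", rid)
        occ_c = rng_c.random((cfg.control_years, cfg.n_lat, cfg.n_lon)) < p0[None, :, :]
        controls[rid] = xr.DataArray(
            occ_c * a[None, :, :], dims=("time", "lat", "lon"),
            coords={"time": CONTROL_YEAR0 + np.arange(cfg.control_years), **coords},
            name="exposure",
            attrs={"hazard": cfg.hazard, "run": rid, "scenario": "picontrol"},
        )
    return SyntheticEnsemble(cfg, fields, controls, gmt, params, mask)


# ---------------------------------------------------------------------------
# demographics
# ---------------------------------------------------------------------------

def gen_demographics(cfg: SynthConfig) -> dict[str, object]:
    """Country demography tables and a gridded population surface.

    Returns ``life_expectancy`` (country, block_start, life_expectancy of
    5-year-olds; 5-year blocks 1950-1955 .. 2015-2020), ``cohort_sizes``
    (country, year 1950:5:2100, age_group, size), ``population`` (time 1860-2100,
    lat, lon) and ``mask``.
    """
    rng = child_rng(cfg.master_seed, "demographics")
    mask = country_mask(cfg)
    countries = np.arange(cfg.n_countries)

    # life expectancy of 5-year-olds: linear country trend + noise, capped so
    # the longest lifetime (birth 2020, +5 applied downstream) ends by 2113
    blocks = np.arange(1950, 2020, 5)
    le_rows = []
    le0 = rng.uniform(*cfg.le_1950_range, size=cfg.n_countries)
    le1 = rng.uniform(*cfg.le_2020_range, size=cfg.n_countries)
    for c in countries:
        trend = le0[c] + (le1[c] - le0[c]) * (blocks - 1950) / (2015 - 1950)
        vals = np.clip(trend + rng.normal(0.0, 0.5, size=blocks.size), 40.0, 83.0)
        for b, v in zip(blocks, vals):
            le_rows.append((int(c), int(b), float(v)))
    life_expectancy = pd.DataFrame(
        le_rows, columns=["country", "block_start", "life_expectancy"]
    )

    # country totals: exponential growth; cohort table shares fixed per country
    pop0 = rng.uniform(*cfg.country_pop_range, size=cfg.n_countries)
    growth = rng.uniform(*cfg.pop_growth_range, size=cfg.n_countries)

    def country_total(c: int, years: np.ndarray) -> np.ndarray:
        return pop0[c] * np.exp(growth[c] * (np.asarray(years, float) - 1950.0))

    age_mid = np.array([a + 2.0 for a in range(0, 100, 5)] + [102.0])
    table_years = np.arange(1950, 2101, 5)
    rows = []
    for c in countries:
        shares = np.exp(-rng.uniform(0.01, 0.03) * age_mid)
        shares /= shares.sum()
        totals = country_total(c, table_years)
        for y, tot in zip(table_years, totals):
            for g, s in zip(AGE_GROUPS, shares):
                rows.append((int(c), int(y), g, float(s * tot)))
    cohort_sizes = pd.DataFrame(rows, columns=["country", "year", "age_group", "size"])

    # gridded population: fixed lognormal cell weights within each country,
    # scaled by the country total each year
    years = np.arange(1860, 2101)
    w = rng.lognormal(0.0, 1.0, size=(cfg.n_lat, cfg.n_lon))
    m = mask.values
    for c in countries:
        sel = m == c
        w[sel] /= w[sel].sum()
    totals = np.stack([country_total(c, years) for c in countries])  # (country, time)
    pop = totals[m, :].transpose(2, 0, 1) * w[None, :, :]
    population = xr.DataArray(
        pop, dims=("time", "lat", "lon"),
        coords={"time": years, "lat": cfg.lat, "lon": cfg.lon}, name="population",
    )
    return {
        "life_expectancy": life_expectancy,
        "cohort_sizes": cohort_sizes,
        "population": population,
        "mask": mask,
    }


# ---------------------------------------------------------------------------
# vulnerability surfaces
# ---------------------------------------------------------------------------

def gen_vulnerability(
    cfg: SynthConfig, population: xr.DataArray | None = None
) -> dict[str, xr.DataArray]:
    """Gridded deprivation index (0-100) and a strictly positive annual GDP series.

    Deprivation is coupled to the per-capita GDP surface through a Gaussian
    copula whose Spearman rank correlation is ``cfg.deprivation_gdp_rank_corr``;
    at -1 the deprivation map is the exact reverse ranking of GDP per capita.
    """
    rng = child_rng(cfg.master_seed, "vulnerability")
    if population is None:
        population = gen_demographics(cfg)["population"]
    shape = (cfg.n_lat, cfg.n_lon)
    coords = {"lat": cfg.lat, "lon": cfg.lon}

    z1 = rng.normal(size=shape)
    gdp_pc = cfg.gdp_pc_median * np.exp(0.5 * z1)  # lognormal per-capita level

    rho_s = cfg.deprivation_gdp_rank_corr
    rho = 2.0 * np.sin(np.pi * rho_s / 6.0)  # Spearman -> Pearson for a Gaussian copula
    z2 = rho * z1 + np.sqrt(max(0.0, 1.0 - rho * rho)) * rng.normal(size=shape)
    deprivation = xr.DataArray(
        100.0 * stats.norm.cdf(z2), dims=("lat", "lon"), coords=coords,
        name="deprivation", attrs={"long_name": "relative deprivation index (0-100)"},
    )

    years = population.time.values
    growth = np.exp(0.01 * (years.astype(float) - years[0]))
    gdp = population * xr.DataArray(
        gdp_pc, dims=("lat", "lon"), coords=coords
    ) * xr.DataArray(growth, dims=("time",), coords={"time": years})
    gdp = gdp.rename("gdp")
    gdp = gdp.where(gdp > 0, 1e-6)  # strictly positive even for empty cells
    return {"deprivation": deprivation, "gdp": gdp}


# ---------------------------------------------------------------------------
# analytic ground truth
# ---------------------------------------------------------------------------

def poisson_binomial_pmf(probs: np.ndarray) -> np.ndarray:
    """PMF of a sum of independent Bernoulli trials.

    ``probs`` has shape (n_trials, n_cells); returns (n_trials + 1, n_cells).
    Exact O(n^2) convolution, vectorized across cells.
    """
    probs = np.atleast_2d(np.asarray(probs, dtype=float))
    n, m = probs.shape
    pmf = np.zeros((n + 1, m))
    pmf[0] = 1.0
    for t in range(n):
        p = probs[t]
        pmf[1:t + 2] = pmf[1:t + 2] * (1.0 - p) + pmf[:t + 1] * p
        pmf[0] *= 1.0 - p
    return pmf


def _scaled_tail(
    pmf: np.ndarray, a: np.ndarray, frac: float, p_last: np.ndarray, q: np.ndarray
) -> np.ndarray:
    """P(a * (K + frac * X) > q) with K ~ pmf columns, X ~ Bernoulli(p_last)."""
    nmax = pmf.shape[0] - 1
    cdf = np.cumsum(pmf, axis=0)

    def tail_at(y: np.ndarray) -> np.ndarray:
        c = np.floor(y + 1e-9).astype(int)  # P(K > y) = P(K >= floor(y)+1)
        out = np.ones_like(y, dtype=float)
        below = c >= 0
        idx = np.clip(c, 0, nmax)
        out[below] = 1.0 - np.take_along_axis(cdf, idx[None, :], axis=0)[0][below]
        out[c >= nmax] = 0.0
        return out

    y0 = q / a
    if frac > 1e-12:
        return (1.0 - p_last) * tail_at(y0) + p_last * tail_at(y0 - frac)
    return tail_at(y0)


def stationary_ule_threshold(
    p0: np.ndarray, a: np.ndarray, life_expectancy: float, percentile: float = 99.99
) -> np.ndarray:
    """Exact population quantile of stationary lifetime exposure per cell.

    Stationary lifetime exposure is ``a * (Binomial(floor(L), p0) + frac *
    Bernoulli(p0))``; the threshold is the smallest support value whose CDF
    reaches ``percentile`` — the population analogue of the nearest-rank rule.
    """
    p0 = np.atleast_1d(np.asarray(p0, float))
    a = np.broadcast_to(np.asarray(a, float), p0.shape)
    nfull = int(np.floor(life_expectancy))
    frac = life_expectancy - nfull
    k = np.arange(nfull + 1)
    pmf_k = stats.binom.pmf(k[:, None], nfull, p0[None, :])  # (nfull+1, m)
    if frac > 1e-12:
        vals = np.concatenate([a[None, :] * k[:, None], a[None, :] * (k[:, None] + frac)])
        probs = np.concatenate([pmf_k * (1.0 - p0)[None, :], pmf_k * p0[None, :]])
    else:
        vals = a[None, :] * k[:, None]
        probs = pmf_k
    order = np.argsort(vals, axis=0, kind="stable")
    vals_s = np.take_along_axis(vals, order, axis=0)
    cdf = np.cumsum(np.take_along_axis(probs, order, axis=0), axis=0)
    hit = cdf >= percentile / 100.0 - 1e-12
    first = hit.argmax(axis=0)
    return np.take_along_axis(vals_s, first[None, :], axis=0)[0]


def true_emergence_probability(
    p0: np.ndarray,
    beta: np.ndarray,
    a: np.ndarray,
    pathway_gmt: pd.Series,
    birth_year: int,
    life_expectancy: float,
    threshold: np.ndarray,
) -> np.ndarray:
    """Exact P(lifetime exposure > threshold) per cell along a GMT pathway."""
    p0 = np.atleast_1d(np.asarray(p0, float))
    beta = np.broadcast_to(np.asarray(beta, float), p0.shape)
    a = np.broadcast_to(np.asarray(a, float), p0.shape)
    threshold = np.broadcast_to(np.asarray(threshold, float), p0.shape)
    years, weights = year_weights(birth_year, life_expectancy)
    years = np.clip(years, pathway_gmt.index.min(), pathway_gmt.index.max())
    w = pathway_gmt.loc[years].values
    probs = np.clip(p0[None, :] + beta[None, :] * w[:, None], 0.0, 1.0)
    frac = float(life_expectancy - np.floor(life_expectancy))
    if frac > 1e-12:
        pmf = poisson_binomial_pmf(probs[:-1])
        p_last = probs[-1]
    else:
        pmf = poisson_binomial_pmf(probs)
        p_last = np.zeros_like(p0)
    return _scaled_tail(pmf, a, frac, p_last, threshold)


def true_cohort_fraction(
    params: dict[str, xr.DataArray],
    mask: xr.DataArray,
    le: pd.DataFrame,
    le_1960: pd.Series | dict,
    cohort_size: xr.DataArray,
    pathways: pd.DataFrame,
    percentile: float = 99.99,
    birth_years: np.ndarray | None = None,
) -> pd.DataFrame:
    """Analytic cohort fraction reaching ULE, per birth year and pathway.

    ``le`` is the annualized country life-expectancy table (index country,
    columns birth years); ``le_1960`` the per-country 1960 value underlying
    the pre-industrial threshold; ``cohort_size`` the gridded birth-cohort
    sizes B(x, b).  Returns columns ``birth_year, pathway, cf_true,
    cf_sd_single_run`` where the SD is the exact standard deviation of a
    single ensemble member's cohort fraction (cells independent).
    """
    m = mask.values.ravel()
    land = m >= 0
    p0 = params["p0"].values.ravel()[land]
    beta = params["beta"].values.ravel()[land]
    a = params["a"].values.ravel()[land]
    cm = m[land]
    if birth_years is None:
        birth_years = np.asarray(le.columns, dtype=int)

    # per-country stationary thresholds (1960 life expectancy)
    thr = np.empty(p0.shape)
    for c in np.unique(cm):
        sel = cm == c
        thr[sel] = stationary_ule_threshold(p0[sel], a[sel], float(le_1960[c]), percentile)

    rows = []
    for pw in pathways.columns:
        g = pathways[pw]
        for b in birth_years:
            bsz = cohort_size.sel(birth_year=int(b)).values.ravel()[land]
            pem = np.empty(p0.shape)
            for c in np.unique(cm):
                sel = cm == c
                pem[sel] = true_emergence_probability(
                    p0[sel], beta[sel], a[sel], g, int(b), float(le.loc[c, b]), thr[sel]
                )
            total = bsz.sum()
            cf = float((bsz * pem).sum() / total)
            var = float((bsz**2 * pem * (1.0 - pem)).sum() / total**2)
            rows.append((int(b), float(pw), cf, np.sqrt(var)))
    return pd.DataFrame(rows, columns=["birth_year", "pathway", "cf_true", "cf_sd_single_run"])


def _mapped_tail(
    p_s: np.ndarray,            # (n_unique_sources, n_cells) occurrence probs
    mult: np.ndarray,           # integer multiplicity per unique source year
    a: np.ndarray,
    frac: float,
    frac_src: int,              # row index of the source year carrying the frac, -1 none
    threshold: np.ndarray,
) -> np.ndarray:
    """Exact P(a * sum_s w_s X_s > threshold) where w_s = mult_s (+ frac for one s).

    Year resampling onto a pathway can pick the same source year for several
    target years, so a lifetime sum is a weighted sum of independent
    Bernoulli draws with integer multiplicities; the death-year fraction
    rides on whichever source year the final target year maps to.
    """
    n_cells = p_s.shape[1]
    full_mult = int(mult.sum())
    pmf = np.zeros((full_mult + 1, n_cells))
    pmf[0] = 1.0
    top = 0
    p_f = np.zeros(n_cells)
    m_f = 0
    for i in range(p_s.shape[0]):
        if i == frac_src:
            p_f = p_s[i]
            m_f = int(mult[i])
            continue
        m = int(mult[i])
        p = p_s[i]
        top += m
        pmf[m:top + 1] = pmf[m:top + 1] * (1.0 - p) + pmf[:top + 1 - m] * p
        pmf[:m] *= 1.0 - p
    cdf = np.cumsum(pmf, axis=0)

    def tail_at(y: np.ndarray) -> np.ndarray:
        c = np.floor(y + 1e-9).astype(int)
        out = np.ones_like(y, dtype=float)
        nb = c >= 0
        idx = np.clip(c, 0, full_mult)
        out[nb] = 1.0 - np.take_along_axis(cdf, idx[None, :], axis=0)[0][nb]
        out[c >= full_mult] = 0.0
        return out

    y0 = threshold / a
    if frac_src >= 0:
        return (1.0 - p_f) * tail_at(y0) + p_f * tail_at(y0 - (m_f + frac))
    return tail_at(y0)


def true_cohort_fraction_mapped(
    params: dict[str, xr.DataArray],
    mask: xr.DataArray,
    gmt: dict[str, pd.Series],
    mappings: dict,
    le: pd.DataFrame,
    le_1960: pd.Series | dict,
    cohort_size: xr.DataArray,
    percentile: float = 99.99,
    birth_years: np.ndarray | None = None,
) -> pd.DataFrame:
    """Exact cohort fraction of the resampled pipeline, per birth year and pathway.

    Unlike :func:`true_cohort_fraction`, which idealizes lifetime years as
    independent draws along the target pathway, this conditions on the
    realized year mappings: a target year inherits the occurrence
    probability of its mapped source year (raw run GMT), and source years
    picked repeatedly contribute one Bernoulli draw with multiplicity.  This
    is the exact sampling distribution of the pipeline's per-run cohort
    fraction, so the ensemble mean should match it to Monte-Carlo precision.

    ``mappings``: (run_id, pathway) -> YearMapping (only valid ones used).
    Returns per (birth_year, pathway): ``cf_true`` (mean over valid runs of
    the per-run expectation) and ``cf_sd_ensemble_mean`` (exact SD of the
    ensemble-mean CF; cells and runs independent).
    """
    m = mask.values.ravel()
    land = m >= 0
    p0 = params["p0"].values.ravel()[land]
    beta = params["beta"].values.ravel()[land]
    a = params["a"].values.ravel()[land]
    cm = m[land]
    if birth_years is None:
        birth_years = np.asarray(le.columns, dtype=int)

    thr = np.empty(p0.shape)
    for c in np.unique(cm):
        sel = cm == c
        thr[sel] = stationary_ule_threshold(p0[sel], a[sel], float(le_1960[c]), percentile)

    by_pathway: dict[float, list] = {}
    for (rid, pw), mp in mappings.items():
        if mp.valid:
            by_pathway.setdefault(float(pw), []).append((rid, mp))

    rows = []
    for pw, runs in sorted(by_pathway.items()):
        for b in birth_years:
            bsz = cohort_size.sel(birth_year=int(b)).values.ravel()[land]
            total = bsz.sum()
            cf_runs, var_runs = [], []
            for rid, mp in runs:
                w_raw = gmt[rid]
                s_of = dict(zip(mp.target_years.tolist(), mp.source_years.tolist()))
                pem = np.empty(p0.shape)
                for c in np.unique(cm):
                    sel = cm == c
                    L = float(le.loc[c, b])
                    years, weights = year_weights(int(b), L)
                    frac = L - math.floor(L)
                    tmax = int(mp.target_years.max())
                    has_frac = frac > 1e-12
                    if years[-1] > tmax:  # mirror the pipeline's truncation
                        keep = years <= tmax
                        years = years[keep]
                        has_frac = False
                        frac = 0.0
                    full_years = years[:-1] if has_frac else years
                    srcs = np.array([s_of[int(y)] for y in full_years])
                    uniq, mult = np.unique(srcs, return_counts=True)
                    if has_frac:
                        sf = s_of[int(years[-1])]
                        if sf not in uniq:
                            uniq = np.append(uniq, sf)
                            mult = np.append(mult, 0)
                        frac_src = int(np.flatnonzero(uniq == sf)[0])
                    else:
                        frac_src = -1
                    w_s = w_raw.loc[uniq].to_numpy(dtype=float)
                    p_s = np.clip(
                        p0[None, sel] + beta[None, sel] * w_s[:, None], 0.0, 1.0
                    )
                    pem[sel] = _mapped_tail(p_s, mult, a[sel], frac, frac_src, thr[sel])
                cf_runs.append(float((bsz * pem).sum() / total))
                var_runs.append(float((bsz**2 * pem * (1 - pem)).sum() / total**2))
            nr = len(cf_runs)
            rows.append((int(b), float(pw), float(np.mean(cf_runs)),
                         float(np.sqrt(np.sum(var_runs)) / nr), nr))
    return pd.DataFrame(
        rows,
        columns=["birth_year", "pathway", "cf_true", "cf_sd_ensemble_mean", "n_runs"],
    )


def simulate_emergence_probability(
    p0: float,
    beta: float,
    a: float,
    pathway_gmt: pd.Series,
    birth_year: int,
    life_expectancy: float,
    threshold: float,
    n_rep: int = 100_000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Brute-force Monte-Carlo estimate of the emergence tail for one cell.

    Independent oracle for :func:`true_emergence_probability`; returns
    (estimate, binomial standard error).
    """
    rng = rng or np.random.default_rng(0)
    years, weights = year_weights(birth_year, life_expectancy)
    years = np.clip(years, pathway_gmt.index.min(), pathway_gmt.index.max())
    p = np.clip(p0 + beta * pathway_gmt.loc[years].values, 0.0, 1.0)
    occ = rng.random((n_rep, p.size)) < p[None, :]
    expo = a * (occ * weights[None, :]).sum(axis=1)
    est = float(np.mean(expo > threshold))
    return est, float(np.sqrt(max(est * (1 - est), 1e-12) / n_rep))


# ---------------------------------------------------------------------------
# on-disk world (NetCDF + CSV + JSON manifest)
# ---------------------------------------------------------------------------

def write_world(path, ensemble: SyntheticEnsemble, demog: dict, vuln: dict) -> None:
    """Write a generated world to ``path`` as NetCDF grids, CSV tables and JSON."""
    from pathlib import Path

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for rid, fld in ensemble.fields.items():
        fld.to_dataset(name="exposure").to_netcdf(path / f"exposure_{rid}.nc", engine="scipy")
    for rid, ctl in ensemble.controls.items():
        ctl.to_dataset(name="exposure").to_netcdf(path / f"control_{rid}.nc", engine="scipy")
    gmt = pd.DataFrame({rid: s for rid, s in ensemble.gmt.items()})
    gmt.rename_axis("year").to_csv(path / "gmt.csv")
    demog["life_expectancy"].to_csv(path / "life_expectancy_blocks.csv", index=False)
    demog["cohort_sizes"].to_csv(path / "cohort_sizes.csv", index=False)
    demog["population"].to_dataset(name="population").to_netcdf(
        path / "population.nc", engine="scipy")
    ensemble.mask.to_dataset(name="country").to_netcdf(path / "country_mask.nc", engine="scipy")
    vuln["deprivation"].to_dataset(name="deprivation").to_netcdf(
        path / "deprivation.nc", engine="scipy")
    vuln["gdp"].to_dataset(name="gdp").to_netcdf(path / "gdp.nc", engine="scipy")
    truth = {
        "config": _cfg_to_jsonable(ensemble.cfg),
        "p0": ensemble.params["p0"].values.tolist(),
        "beta": ensemble.params["beta"].values.tolist(),
        "exposed_fraction": ensemble.params["a"].values.tolist(),
    }
    (path / "ground_truth.json").write_text(json.dumps(truth, indent=1))


def _cfg_to_jsonable(cfg: SynthConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["runs"] = [r.run_id for r in cfg.runs]
    return d


def read_world(path) -> tuple[SyntheticEnsemble, dict, dict]:
    """Read back a world written by :func:`write_world`."""
    from pathlib import Path

    path = Path(path)
    truth = json.loads((path / "ground_truth.json").read_text())
    c = dict(truth["config"])
    c["runs"] = [RunSpec(*rid.split("_")) for rid in c["runs"]]
    for k in ("p0_range", "beta_range", "exposed_fraction_range", "le_1950_range",
              "le_2020_range", "country_pop_range", "pop_growth_range", "birth_years"):
        c[k] = tuple(c[k])
    cfg = SynthConfig(**c)
    fields, controls = {}, {}
    for run in cfg.runs:
        rid = run.run_id
        fields[rid] = xr.open_dataset(path / f"exposure_{rid}.nc", engine="scipy")["exposure"].load()
        controls[rid] = xr.open_dataset(path / f"control_{rid}.nc", engine="scipy")["exposure"].load()
    gmt_df = pd.read_csv(path / "gmt.csv", index_col="year")
    gmt = {rid: gmt_df[rid] for rid in gmt_df.columns}
    mask = xr.open_dataset(path / "country_mask.nc", engine="scipy")["country"].load()
    coords = {"lat": mask.lat, "lon": mask.lon}
    params = {
        "p0": xr.DataArray(np.asarray(truth["p0"]), dims=("lat", "lon"), coords=coords),
        "beta": xr.DataArray(np.asarray(truth["beta"]), dims=("lat", "lon"), coords=coords),
        "a": xr.DataArray(np.asarray(truth["exposed_fraction"]), dims=("lat", "lon"),
                          coords=coords),
    }
    ensemble = SyntheticEnsemble(cfg, fields, controls, gmt, params, mask)
    demog = {
        "life_expectancy": pd.read_csv(path / "life_expectancy_blocks.csv"),
        "cohort_sizes": pd.read_csv(path / "cohort_sizes.csv"),
        "population": xr.open_dataset(path / "population.nc", engine="scipy")["population"].load(),
        "mask": mask,
    }
    vuln = {
        "deprivation": xr.open_dataset(path / "deprivation.nc", engine="scipy")["deprivation"].load(),
        "gdp": xr.open_dataset(path / "gdp.nc", engine="scipy")["gdp"].load(),
    }
    return ensemble, demog, vuln
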