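"""Pre-industrial baseline bootstrap, ULE thresholds and cohort fractions.

The null distribution of lifetime exposure "in a world without climate
change" is built per grid cell by resampling years with replacement from
long stationary pre-industrial control simulations, assuming the 1960 life
expectancy of the cell's country.  The 99.99th nearest-rank percentile of
the pooled (cross-run) sample is the cell's threshold of unprecedented
lifetime exposure (ULE); a cohort at a cell emerges when its projected
lifetime exposure strictly exceeds it, and the whole birth cohort of the
cell then counts as emerged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats

from .util import child_rng, get_logger, nearest_rank_percentile, year_weights

log = get_logger("emergence")

DEFAULT_N_BOOT = 10_000
DEFAULT_PERCENTILE = 99.99
MIN_CONTROL_YEARS = 239


@dataclass
class BaselineSample:
    """Pooled bootstrap sample of pre-industrial lifetime exposures per cell."""

    samples: np.ndarray              # (n_total, lat, lon)
    lat: np.ndarray
    lon: np.ndarray
    n_boot: int                      # per control run
    n_runs: int
    seed: int
    le_basis: dict                   # country -> life expectancy used (1960)

    @property
    def size(self) -> int:
        return self.samples.shape[0]

    def threshold(self, percentile: float = DEFAULT_PERCENTILE) -> xr.DataArray:
        return ule_threshold(self, percentile)


def _bootstrap_lifetimes(
    ctrl: np.ndarray,               # (n_years, n_cells)
    life_expectancy: float,
    n_boot: int,
    rng: np.random.Generator,
    independent_cells: bool = False,
) -> np.ndarray:
    """n_boot lifetime sums resampled iid with replacement from control years.

    By default one resampled year sequence per replicate is applied to every
    cell at once (bootstrapping maps, preserving spatial coherence); with
    ``independent_cells`` each cell draws its own sequence.
    """
    n_years, n_cells = ctrl.shape
    nfull = int(math.floor(life_expectancy))
    frac = life_expectancy - nfull
    ndraw = nfull + (1 if frac > 1e-12 else 0)
    if independent_cells:
        out = np.empty((n_boot, n_cells))
        for j in range(n_cells):
            idx = rng.integers(0, n_years, size=(n_boot, ndraw))
            vals = ctrl[idx, j]
            s = vals[:, :nfull].sum(axis=1)
            if frac > 1e-12:
                s += frac * vals[:, -1]
            out[:, j] = s
        return out
    # shared year sequence per replicate: accumulate draw counts per year,
    # then one matmul against the control maps
    idx = rng.integers(0, n_years, size=(n_boot, ndraw))
    counts = np.zeros((n_boot, n_years))
    rows = np.repeat(np.arange(n_boot), nfull)
    np.add.at(counts, (rows, idx[:, :nfull].ravel()), 1.0)
    if frac > 1e-12:
        np.add.at(counts, (np.arange(n_boot), idx[:, -1]), frac)
    return counts @ ctrl


def bootstrap_preindustrial(
    controls: dict[str, xr.DataArray],
    mask: xr.DataArray,
    le_1960: dict | pd.Series,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    percentile: float = DEFAULT_PERCENTILE,
    independent_cells: bool = False,
    min_control_years: int = MIN_CONTROL_YEARS,
) -> BaselineSample:
    """Pool ``n_boot`` bootstrapped lifetime exposures per control run and cell.

    Each control contributes ``n_boot`` lifetimes formed by drawing
    ``ceil(L)`` years iid with replacement (1960 life expectancy L of the
    cell's country, fractional final year weighted); samples are pooled
    across runs, so the pooled size is ``n_runs * n_boot``.
    """
    if not controls:
        raise ValueError("no control runs")
    m = mask.values
    pooled = np.zeros((len(controls) * n_boot, *m.shape))
    countries = [int(c) for c in np.unique(m[m >= 0])]
    missing = [c for c in countries if c not in le_1960]
    if missing:
        raise ValueError(f"1960 life expectancy missing for countries {missing}")
    eff_n = len(controls) * n_boot
    if eff_n * (1.0 - percentile / 100.0) < 4.0:
        log.warning(
            "pooled sample of %d gives < 4 expected exceedances at the %.2f "
            "percentile; threshold estimates may be unreliable", eff_n, percentile,
        )
    for ri, (rid, ctl_da) in enumerate(sorted(controls.items())):
        ctl_full = ctl_da.transpose("time", "lat", "lon").values
        if ctl_full.shape[0] < min_control_years:
            raise ValueError(
                f"control {rid} has {ctl_full.shape[0]} years; "
                f"at least {min_control_years} required"
            )
        block = np.zeros((n_boot, *m.shape))
        for c in countries:
            sel = m == c
            rng = child_rng(seed, "bootstrap", rid, c)
            block[:, sel] = _bootstrap_lifetimes(
                ctl_full[:, sel], float(le_1960[c]), n_boot, rng,
                independent_cells=independent_cells,
            )
        pooled[ri * n_boot:(ri + 1) * n_boot] = block
    return BaselineSample(
        samples=pooled, lat=mask.lat.values, lon=mask.lon.values,
        n_boot=n_boot, n_runs=len(controls), seed=seed,
        le_basis={c: float(le_1960[c]) for c in countries},
    )


def ule_threshold(
    sample: BaselineSample | np.ndarray, percentile: float = DEFAULT_PERCENTILE
) -> xr.DataArray | np.ndarray:
    """Nearest-rank percentile of the pooled sample — always a sample element."""
    if isinstance(sample, BaselineSample):
        thr = nearest_rank_percentile(sample.samples, percentile, axis=0)
        return xr.DataArray(
            thr, dims=("lat", "lon"), coords={"lat": sample.lat, "lon": sample.lon},
            name="ule_threshold", attrs={"percentile": percentile,
                                         "pooled_sample_size": sample.size},
        )
    return nearest_rank_percentile(np.asarray(sample), percentile, axis=0)


def detect_emergence(
    lifetime_exposure: xr.DataArray, threshold: xr.DataArray
) -> xr.DataArray:
    """Strict exceedance: a cohort emerges where E(x, b) > T(x)."""
    return (lifetime_exposure > threshold).rename("emerged")


def age_of_emergence(
    trajectory: xr.DataArray, threshold: xr.DataArray
) -> xr.DataArray:
    """First age at which the running cumulative exposure exceeds T; NaN if never."""
    exceeded = trajectory > threshold
    any_exc = exceeded.any("age")
    first = exceeded.argmax("age")
    return first.where(any_exc).rename("age_of_emergence")


def tally_emerged(
    emerged: xr.DataArray, cohort_size: xr.DataArray, mask: xr.DataArray
) -> tuple[float, pd.Series]:
    """Emerged-people count, global and per country.

    All-or-nothing per cell: an emerged cell contributes its entire birth
    cohort.  Returns ``(global_count, per_country)``; the country counts sum
    to the global count exactly.
    """
    contrib = (emerged * cohort_size).values
    m = mask.values
    countries = np.unique(m[m >= 0])
    per_country = pd.Series(
        {int(c): float(contrib[m == c].sum()) for c in countries}, name="emerged"
    )
    return float(per_country.sum()), per_country


def cohort_fraction(counts: float | np.ndarray, totals: float | np.ndarray):
    """CF = emerged people / total cohort size; zero totals flagged as NaN."""
    counts = np.asarray(counts, dtype=float)
    totals = np.asarray(totals, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        cf = np.where(totals > 0, counts / np.where(totals > 0, totals, 1.0), np.nan)
    if np.any(totals <= 0):
        log.warning("zero cohort total encountered; CF undefined there")
    return cf if cf.ndim else float(cf)


def ensemble_cf_stats(per_run: pd.DataFrame) -> pd.DataFrame:
    """Ensemble statistics of CF across valid runs.

    ``per_run``: columns birth_year, pathway, run, cf.  Returns per
    (birth_year, pathway): mean, median, q25, q75, min, max, n_runs.
    NaN CFs (undefined cohorts) are excluded from aggregation.
    """
    d = per_run.dropna(subset=["cf"])
    g = d.groupby(["birth_year", "pathway"])["cf"]
    out = g.agg(
        cf_mean="mean", cf_median="median",
        cf_q25=lambda s: s.quantile(0.25), cf_q75=lambda s: s.quantile(0.75),
        cf_min="min", cf_max="max", n_runs="count",
    ).reset_index()
    return out


def restrict_to_exposed_regions(fields: list[xr.DataArray]) -> xr.DataArray:
    """Mask of cells exposed at least once across the whole ensemble.

    Used for hazards confined to particular regions (e.g. tropical
    cyclones): cohort-fraction denominators are then restricted to cohort
    members living inside the mask.
    """
    if not fields:
        raise ValueError("need at least one exposure field")
    any_mask = None
    for f in fields:
        m = (f > 0).any("time")
        any_mask = m if any_mask is None else (any_mask | m)
    if not bool(any_mask.any()):
        raise ValueError("no cell is ever exposed; restricted CF denominator undefined")
    return any_mask.rename("exposed_region")


def rebased_cohort_fraction(
    emerged: xr.DataArray,
    cohort_size: xr.DataArray,
    region: xr.DataArray,
) -> float:
    """CF with both numerator and denominator restricted to the exposed region."""
    num = float((emerged * cohort_size).where(region, 0.0).sum())
    den = float(cohort_size.where(region, 0.0).sum())
    if den <= 0:
        raise ValueError("no cohort population inside the exposed region")
    return num / den


@dataclass
class SignificanceResult:
    statistic: float
    pvalue: float
    significant: bool
    method: str
    note: str = ""


def ensemble_significance(
    group_a: np.ndarray, group_b: np.ndarray, alpha: float = 0.05
) -> SignificanceResult:
    """Two-sided location comparison across ensemble members.

    Welch's unequal-variance t-test; when either group has zero variance the
    t statistic is undefined, so an exact two-sided Mann-Whitney rank test is
    used instead.  Two identical constant groups are reported as not
    significant with a note.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 ensemble members per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0 and a.mean() == b.mean():
        return SignificanceResult(0.0, 1.0, False, "degenerate",
                                  "identical constant groups")
    if va == 0.0 or vb == 0.0:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        return SignificanceResult(
            float(res.statistic), float(res.pvalue), bool(res.pvalue < alpha),
            "mannwhitney-exact", "zero-variance group; rank-test fallback",
        )
    res = stats.ttest_ind(a, b, equal_var=False)
    return SignificanceResult(
        float(res.statistic), float(res.pvalue), bool(res.pvalue < alpha), "welch-t"
    )


# ---------------------------------------------------------------------------
# threshold calibration experiment
# ---------------------------------------------------------------------------

def calibration_experiment(
    n_cells: int = 100,
    control_years: int = 639,
    p_occurrence: float = 0.01,
    life_expectancy: float = 60.0,
    n_boot: int = 40_000,
    n_validate: int = 10_000,
    percentile: float = DEFAULT_PERCENTILE,
    seed: int = 0,
) -> float:
    """Non-exceedance calibration of the bootstrap ULE threshold.

    For each of ``n_cells`` independent cells: simulate a stationary control
    of iid annual Bernoulli occurrences with unit exposed fraction, bootstrap
    ``n_boot`` lifetime exposures by resampling control years with
    replacement, take the nearest-rank ``percentile`` threshold, then draw
    ``n_validate`` fresh lifetimes by the same resampling scheme and record
    the percentage that does not strictly exceed the threshold.  Returns the
    mean percentage over cells — which should approach ``percentile`` (the
    "one in ten thousand" design rate) from above for a well-calibrated
    threshold on this discrete exposure distribution.
    """
    nfull = int(math.floor(life_expectancy))
    frac = life_expectancy - nfull
    ndraw = nfull + (1 if frac > 1e-12 else 0)
    pct = np.empty(n_cells)
    for j in range(n_cells):
        rng = child_rng(seed, "calibration", j)
        ctrl = (rng.random(control_years) < p_occurrence).astype(float)

        def lifetimes(n: int) -> np.ndarray:
            idx = rng.integers(0, control_years, size=(n, ndraw))
            vals = ctrl[idx]
            s = vals[:, :nfull].sum(axis=1)
            if frac > 1e-12:
                s += frac * vals[:, -1]
            return s

        thr = nearest_rank_percentile(lifetimes(n_boot), percentile)
        fresh = lifetimes(n_validate)
        pct[j] = 100.0 * np.mean(~(fresh > thr))
    return float(pct.mean())
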