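"""Warming-level pathways and year resampling of exposure projections.

Builds incrementally warming GMT pathways (1.5-3.5 degC by 2100 at 0.1 degC
steps) by interpolating between anchor trajectories, and maps each forcing
run's years onto each pathway by matching 21-year-smoothed warming levels.
A mapping is only valid when the worst year-wise warming mismatch stays
within 0.2 degC, which progressively thins the usable ensemble for the
hottest pathways.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .util import get_logger

log = get_logger("gmt")

DEFAULT_WINDOW = 21
DEFAULT_CONSTRAINT = 0.2  # degC
ANALYSIS_YEARS = (1960, 2113)


def smooth_gmt(series: pd.Series, window: int = DEFAULT_WINDOW) -> pd.Series:
    """Centred rolling mean; near the edges the window shrinks symmetrically.

    At index ``i`` the half-width is ``min(window//2, i, n-1-i)``, so the
    first and last years are unsmoothed rather than discarded.  A series
    shorter than the window collapses to its full mean with a warning.
    """
    x = series.to_numpy(dtype=float)
    n = x.size
    if n < window:
        log.warning(
            "GMT series of length %d shorter than %d-year window; using full mean",
            n, window,
        )
        return pd.Series(np.full(n, x.mean()), index=series.index, name=series.name)
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(x)])
    i = np.arange(n)
    h = np.minimum(half, np.minimum(i, n - 1 - i))
    out = (csum[i + h + 1] - csum[i - h]) / (2 * h + 1)
    return pd.Series(out, index=series.index, name=series.name)


def build_pathways(
    anchors: pd.DataFrame,
    lo: float = 1.5,
    hi: float = 3.5,
    step: float = 0.1,
) -> pd.DataFrame:
    """Target GMT pathways by year-wise interpolation between anchor trajectories.

    ``anchors``: DataFrame indexed by year, one column per anchor trajectory.
    Each target level is interpolated between the two anchors bracketing it,
    with weights set by the anchors' year-2100 values; an anchor sitting
    exactly at a target level passes through unchanged.  Returns a DataFrame
    with one column per target level (defaults: 1.5 .. 3.5 at 0.1 -> 21).
    """
    if anchors.shape[1] < 2:
        raise ValueError("need at least 2 anchor trajectories")
    if 2100 not in anchors.index:
        raise ValueError("anchor trajectories must cover year 2100")
    end = anchors.loc[2100].to_numpy(dtype=float)
    order = np.argsort(end)
    end = end[order]
    cols = anchors.columns[order]
    if np.any(np.diff(end) <= 0):
        raise ValueError("anchor 2100 levels must be distinct")

    n = int(round((hi - lo) / step)) + 1
    targets = np.round(lo + step * np.arange(n), 10)
    out = {}
    for t in targets:
        if t < end[0] - 1e-9 or t > end[-1] + 1e-9:
            raise ValueError(
                f"target level {t} outside anchor span [{end[0]:.3f}, {end[-1]:.3f}]"
            )
        j = int(np.searchsorted(end, t))
        if j < end.size and abs(end[j] - t) < 1e-9:
            out[float(t)] = anchors[cols[j]].to_numpy(dtype=float)
            continue
        w = (t - end[j - 1]) / (end[j] - end[j - 1])
        out[float(t)] = (
            (1.0 - w) * anchors[cols[j - 1]].to_numpy(dtype=float)
            + w * anchors[cols[j]].to_numpy(dtype=float)
        )
    return pd.DataFrame(out, index=anchors.index.copy())


@dataclass
class YearMapping:
    """Resampling of one run's years onto one target pathway."""

    run_id: str
    pathway: float
    target_years: np.ndarray
    source_years: np.ndarray
    max_discrepancy: float          # D = max_t |W_smooth(s(t)) - g(t)|, degC
    constraint: float = DEFAULT_CONSTRAINT

    @property
    def valid(self) -> bool:
        return self.max_discrepancy <= self.constraint + 1e-12

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "target_year": self.target_years,
            "source_year": self.source_years,
            "run": self.run_id,
            "pathway": self.pathway,
        })


def map_years(
    w_smoothed: pd.Series,
    pathway: pd.Series,
    run_id: str = "",
    pathway_id: float | None = None,
    constraint: float = DEFAULT_CONSTRAINT,
    target_years: tuple[int, int] = ANALYSIS_YEARS,
) -> YearMapping:
    """For each target year pick the source year whose smoothed warming is
    closest to the pathway's level; ties go to the earliest source year.

    The mapping is flagged invalid (never raised) when the worst mismatch D
    exceeds the constraint.
    """
    tgt = pathway.loc[(pathway.index >= target_years[0]) & (pathway.index <= target_years[1])]
    src = w_smoothed.to_numpy(dtype=float)
    diffs = np.abs(src[None, :] - tgt.to_numpy(dtype=float)[:, None])
    pick = diffs.argmin(axis=1)  # argmin returns the first (earliest) minimum
    d = float(diffs[np.arange(pick.size), pick].max())
    pid = float(pathway_id) if pathway_id is not None else float(pathway.name or np.nan)
    return YearMapping(
        run_id=run_id,
        pathway=pid,
        target_years=tgt.index.to_numpy(dtype=int),
        source_years=w_smoothed.index.to_numpy(dtype=int)[pick],
        max_discrepancy=d,
        constraint=constraint,
    )


def resample_exposure(field: xr.DataArray, mapping: YearMapping) -> xr.DataArray:
    """Relabel the field's years onto the pathway's target years.

    Every output year carries (bit-identically) the field of its mapped
    source year.  Refuses invalid mappings.
    """
    if not mapping.valid:
        raise ValueError(
            f"mapping {mapping.run_id} -> pathway {mapping.pathway} is invalid: "
            f"max warming discrepancy {mapping.max_discrepancy:.3f} degC exceeds "
            f"the {mapping.constraint:.2f} degC constraint"
        )
    have = set(field.time.values.astype(int).tolist())
    missing = sorted(set(mapping.source_years.tolist()) - have)
    if missing:
        raise ValueError(f"field is missing mapped source year(s) {missing[:5]} ...")
    out = field.sel(time=mapping.source_years)
    out = out.assign_coords(time=mapping.target_years)
    out.attrs.update(
        pathway=mapping.pathway,
        source_run=mapping.run_id,
        max_warming_discrepancy=mapping.max_discrepancy,
    )
    return out


@dataclass
class PathwayEnsemble:
    """Valid (run, pathway) mappings for one ensemble of runs."""

    mappings: dict[tuple[str, float], YearMapping] = field(default_factory=dict)

    def valid_runs(self, pathway: float) -> list[str]:
        return [r for (r, p), m in self.mappings.items() if p == pathway and m.valid]

    def ensemble_sizes(self) -> pd.Series:
        pws = sorted({p for _, p in self.mappings})
        return pd.Series({p: len(self.valid_runs(p)) for p in pws}, name="n_runs")


def map_ensemble(
    gmt: dict[str, pd.Series],
    pathways: pd.DataFrame,
    window: int = DEFAULT_WINDOW,
    constraint: float = DEFAULT_CONSTRAINT,
) -> PathwayEnsemble:
    """Smooth every run's GMT and map it onto every pathway."""
    ens = PathwayEnsemble()
    for rid, w in gmt.items():
        ws = smooth_gmt(w, window)
        for p in pathways.columns:
            ens.mappings[(rid, float(p))] = map_years(
                ws, pathways[p], run_id=rid, pathway_id=float(p), constraint=constraint
            )
    sizes = ens.ensemble_sizes()
    log.info("valid ensemble sizes per pathway: %s", sizes.to_dict())
    return ens


def mappings_to_csv(ens: PathwayEnsemble, path) -> None:
    rows = []
    for (rid, p), m in sorted(ens.mappings.items()):
        df = m.to_frame()
        df["max_discrepancy"] = m.max_discrepancy
        df["valid"] = m.valid
        rows.append(df)
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)
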