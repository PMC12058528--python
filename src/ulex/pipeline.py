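"""End-to-end orchestration: config, staged execution, provenance manifest.

A single run configuration (YAML) drives every stage — synthetic-world
generation or input loading, demographic annualization, pathway
construction and year mapping, the pre-industrial bootstrap baseline,
emergence detection and cohort-fraction aggregation, and vulnerability
stratification — writing CSV tables, NetCDF grids and a JSON manifest that
records seeds, ensemble membership per pathway and every methodological
setting in force.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from . import demographics as demo
from . import emergence as emg
from . import gmt
from . import lifetime as lt
from . import synthetic as syn
from . import vulnerability as vul
from .util import get_logger

log = get_logger("pipeline")

METHOD_SETTINGS = {
    "emergence_comparison": "strict (E > T)",
    "threshold_rule": "nearest-rank percentile of the pooled cross-run sample",
    "bootstrap": "years drawn iid with replacement; fractional final year weighted",
    "gmt_smoothing": "centred rolling mean, window shrinks symmetrically at edges",
    "year_mapping_tie_break": "earliest source year",
    "pathway_interpolation": "two bracketing anchors, weights from 2100 levels",
    "headline_statistic": "ensemble mean (median/quartiles/range retained)",
    "significance_test": "Welch two-sample t, exact rank-sum fallback at zero variance",
}


class EmptyEnsembleError(RuntimeError):
    """No valid ensemble member remains for at least one requested pathway."""


@dataclass
class RunConfig:
    """Everything one pipeline run needs; exactly one input source."""

    synthetic: dict | None = None          # SynthConfig keyword overrides
    inputs: str | None = None              # path to a previously written world
    hazards: list[str] = field(default_factory=lambda: ["heatwave"])
    birth_year_range: tuple[int, int] = (1960, 2020)
    pathway_lo: float = 1.5
    pathway_hi: float = 3.5
    pathway_step: float = 0.1
    anchor_levels: tuple[float, ...] = (1.5, 2.5, 3.5)
    gmt_window: int = 21
    gmt_constraint: float = 0.2
    n_boot: int = 10_000
    percentile: float = 99.99
    seed: int = 0
    strata_indicator: str = "deprivation"  # or "gdp"
    strata_k: int = 5
    strata_pathway: float | None = None    # default: hottest requested pathway
    strata_birth_years: list[int] | None = None
    restrict_to_exposed: bool = False

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.inputs is None):
            raise ValueError("exactly one of 'synthetic' or 'inputs' must be given")
        if not 50.0 < self.percentile < 100.0:
            raise ValueError(f"percentile must lie in (50, 100), got {self.percentile}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("birth_year_range", "anchor_levels"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def synth_config(self) -> syn.SynthConfig:
        kw = dict(self.synthetic or {})
        kw.setdefault("master_seed", self.seed)
        kw.setdefault("birth_years", self.birth_year_range)
        if "runs" in kw and kw["runs"] and isinstance(kw["runs"][0], str):
            kw["runs"] = [syn.RunSpec(*r.split("_")) for r in kw["runs"]]
        elif "n_runs" in kw:
            kw["runs"] = syn.default_runs(int(kw.pop("n_runs")))
        return syn.SynthConfig(**kw)


# ---------------------------------------------------------------------------
# input validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    ok: bool
    messages: list[str]

    def __str__(self) -> str:
        head = "inputs OK" if self.ok else "input validation FAILED"
        return "\n".join([head] + [f"  - {m}" for m in self.messages])


def validate_inputs(path) -> ValidationReport:
    """Schema, range and consistency checks on a world directory."""
    path = Path(path)
    msgs: list[str] = []
    ok = True

    def fail(msg: str) -> None:
        nonlocal ok
        ok = False
        msgs.append(msg)

    try:
        ensemble, demog, vuln_maps = syn.read_world(path)
    except Exception as e:  # noqa: BLE001 - report, don't crash
        return ValidationReport(False, [f"cannot read world at {path}: {e}"])

    for kind, fields in (("exposure", ensemble.fields), ("control", ensemble.controls)):
        for rid, fld in fields.items():
            vals = fld.values
            if np.any(vals < 0) or np.any(vals > 1):
                ij = np.argwhere((vals < 0) | (vals > 1))[0]
                year = int(fld.time.values[ij[0]])
                fail(f"{kind} field {rid}: fraction outside [0, 1] at "
                     f"cell (lat={ij[1]}, lon={ij[2]}), year {year}")
            t = fld.time.values.astype(int)
            if np.any(np.diff(t) != 1):
                fail(f"{kind} field {rid}: time axis not contiguous annual")

    ct = demog["cohort_sizes"]
    expected_groups = set(syn.AGE_GROUPS)
    for (c, y), grp in ct.groupby(["country", "year"]):
        missing = expected_groups - set(grp["age_group"])
        if missing:
            fail(f"cohort table: country {c}, year {y} missing age group(s) "
                 f"{sorted(missing)}")
            break
    le = demog["life_expectancy"]
    for c, grp in le.groupby("country"):
        missing = set(demo.LE_BLOCKS) - set(grp["block_start"])
        if missing:
            fail(f"life-expectancy table: country {c} missing block(s) {sorted(missing)}")

    m = demog["mask"].values
    table_countries = set(int(x) for x in ct["country"].unique())
    mask_countries = set(int(x) for x in np.unique(m[m >= 0]))
    orphans = mask_countries - table_countries
    if orphans:
        fail(f"mask countries {sorted(orphans)} absent from demographic tables")

    dep = vuln_maps["deprivation"].values
    if np.any((dep < 0) | (dep > 100)):
        fail("deprivation index outside [0, 100]")
    if np.any(vuln_maps["gdp"].values <= 0):
        fail("GDP series not strictly positive")

    if ok:
        msgs.append(f"{len(ensemble.fields)} exposure run(s), "
                    f"{len(mask_countries)} countries, grid "
                    f"{m.shape[0]}x{m.shape[1]}")
    return ValidationReport(ok, msgs)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _load_world(cfg: RunConfig):
    if cfg.inputs is not None:
        return syn.read_world(cfg.inputs)
    scfg = cfg.synth_config()
    ensemble = syn.gen_exposure_ensemble(scfg)
    demog = syn.gen_demographics(scfg)
    vuln_maps = syn.gen_vulnerability(scfg, demog["population"])
    return ensemble, demog, vuln_maps


def run_pipeline(cfg: RunConfig, outdir) -> dict:
    """Execute every stage and write the artifact bundle under ``outdir``.

    Returns a dict with the main in-memory results (cf tables, thresholds,
    manifest).  Raises :class:`EmptyEnsembleError` after writing all outputs
    if any requested pathway ends up with no valid ensemble member.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    timings: dict[str, float] = {}

    def tick(stage: str) -> None:
        now = time.time()
        timings[stage] = round(now - tick.last, 3)
        tick.last = now
        log.info("stage %-12s %.2fs", stage, timings[stage])

    tick.last = t0

    ensemble, demog, vuln_maps = _load_world(cfg)
    tick("inputs")

    # --- demographics -----------------------------------------------------
    cd = demo.build_country_demography(
        demog["life_expectancy"], demog["cohort_sizes"], cfg.birth_year_range
    )
    population = demo.extrapolate_population(demog["population"], demo.FINAL_YEAR)
    birth_years = np.arange(cfg.birth_year_range[0], cfg.birth_year_range[1] + 1)
    cohort_size = demo.cohort_size_at_grid(population, cd.shares, demog["mask"], birth_years)
    totals = cohort_size.sum(("lat", "lon"))
    tick("demographics")

    # --- pathways and year mappings ---------------------------------------
    scfg = ensemble.cfg
    anchors = syn.gen_gmt_anchors(scfg, tuple(cfg.anchor_levels))
    pathways = gmt.build_pathways(anchors, cfg.pathway_lo, cfg.pathway_hi, cfg.pathway_step)
    ens = gmt.map_ensemble(ensemble.gmt, pathways,
                           window=cfg.gmt_window, constraint=cfg.gmt_constraint)
    sizes = ens.ensemble_sizes()
    empty = [p for p, n in sizes.items() if n == 0]
    pathways.to_csv(outdir / "pathways.csv")
    gmt.mappings_to_csv(ens, outdir / "year_mappings.csv")
    tick("pathways")

    # --- pre-industrial baseline ------------------------------------------
    le_1960 = cd.le[cfg.birth_year_range[0]]
    baseline = emg.bootstrap_preindustrial(
        ensemble.controls, demog["mask"], le_1960,
        n_boot=cfg.n_boot, seed=cfg.seed, percentile=cfg.percentile,
        min_control_years=min(emg.MIN_CONTROL_YEARS, scfg.control_years),
    )
    threshold = baseline.threshold(cfg.percentile)
    threshold.to_dataset(name="ule_threshold").to_netcdf(
        outdir / "ule_threshold.nc", engine="scipy")
    tick("baseline")

    # --- emergence and cohort fractions ------------------------------------
    region = None
    if cfg.restrict_to_exposed:
        region = emg.restrict_to_exposed_regions(list(ensemble.fields.values()))
        region.astype(np.int8).to_dataset(name="exposed_region").to_netcdf(
            outdir / "exposed_region.nc", engine="scipy")

    per_run_rows = []
    country_rows = []
    strata_pw = cfg.strata_pathway if cfg.strata_pathway is not None else float(
        pathways.columns.max())
    emerged_store: dict[tuple[int, str], xr.DataArray] = {}
    for p in pathways.columns:
        runs = ens.valid_runs(float(p))
        for rid in runs:
            mapping = ens.mappings[(rid, float(p))]
            field_p = gmt.resample_exposure(ensemble.fields[rid], mapping)
            expo = lt.lifetime_exposure_grid(field_p, demog["mask"], cd.le, birth_years)
            emerged = emg.detect_emergence(expo, threshold)
            for b in birth_years:
                em_b = emerged.sel(birth_year=int(b))
                csz = cohort_size.sel(birth_year=int(b))
                count, per_country = emg.tally_emerged(em_b, csz, demog["mask"])
                tot = float(totals.sel(birth_year=int(b)))
                if region is not None:
                    cf = emg.rebased_cohort_fraction(em_b, csz, region)
                else:
                    cf = emg.cohort_fraction(count, tot)
                per_run_rows.append((int(b), float(p), rid, count, tot, cf))
                ctot = pd.Series({
                    int(c): float(csz.values[demog["mask"].values == c].sum())
                    for c in per_country.index})
                for c in per_country.index:
                    country_rows.append((int(b), float(p), rid, int(c),
                                         per_country[c], ctot[c]))
                if float(p) == strata_pw:
                    emerged_store[(int(b), rid)] = em_b
    per_run = pd.DataFrame(
        per_run_rows, columns=["birth_year", "pathway", "run", "emerged", "total", "cf"])
    cf_stats = emg.ensemble_cf_stats(per_run)
    per_run.to_csv(outdir / "cf_per_run.csv", index=False)
    cf_stats.to_csv(outdir / "cf_stats.csv", index=False)

    country = pd.DataFrame(
        country_rows,
        columns=["birth_year", "pathway", "run", "country", "emerged", "total"])
    country["cf"] = country["emerged"] / country["total"].where(country["total"] > 0)
    country_cf = (country.groupby(["birth_year", "pathway", "country"])["cf"]
                  .mean().reset_index())
    country_cf.to_csv(outdir / "cf_per_country.csv", index=False)
    summary = country_cf.groupby(["birth_year", "pathway"])["cf"].agg(
        n_countries="count",
        n_ge_50=lambda s: int((s >= 0.5).sum()),
        n_ge_90=lambda s: int((s >= 0.9).sum()),
        n_eq_100=lambda s: int((s >= 1.0).sum()),
    ).reset_index()
    summary.to_csv(outdir / "cf_country_summary.csv", index=False)
    tick("emergence")

    # --- vulnerability strata ----------------------------------------------
    strata_df = pd.DataFrame()
    strata_years = cfg.strata_birth_years or [int(b) for b in birth_years[::5]]
    if emerged_store:
        comparisons = []
        for b in strata_years:
            csz = cohort_size.sel(birth_year=int(b))
            if cfg.strata_indicator == "deprivation":
                indicator = vuln_maps["deprivation"]
            else:
                indicator = vul.lifetime_mean_gdp(
                    vuln_maps["gdp"], population, cd.le, demog["mask"], int(b))
            bins = vul.population_weighted_bins(indicator, csz, cfg.strata_k, int(b))
            emerged_by_run = {rid: em for (by, rid), em in emerged_store.items()
                              if by == int(b)}
            if len(emerged_by_run) >= 2:
                comparisons.append(vul.strata_ule(emerged_by_run, bins, csz))
        if comparisons:
            strata_df = vul.strata_table(comparisons)
            strata_df.to_csv(outdir / "strata.csv", index=False)
    tick("strata")

    manifest = {
        "config": dataclasses.asdict(cfg),
        "synthetic_config": syn._cfg_to_jsonable(scfg),
        "seed": cfg.seed,
        "method_settings": METHOD_SETTINGS,
        "pooled_baseline_sample_size": baseline.size,
        "ensemble_membership": {str(p): ens.valid_runs(float(p))
                                for p in pathways.columns},
        "empty_ensembles": [float(p) for p in empty],
        "n_pathways": int(pathways.shape[1]),
        "timings_s": timings,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    log.info("pipeline finished in %.1fs", time.time() - t0)

    result = {
        "cf_per_run": per_run, "cf_stats": cf_stats, "country_cf": country_cf,
        "country_summary": summary, "threshold": threshold, "strata": strata_df,
        "manifest": manifest, "pathways": pathways, "ensemble": ens,
    }
    if empty:
        raise EmptyEnsembleError(
            f"no valid ensemble member for pathway(s) {empty}; "
            f"outputs written to {outdir}")
    return result
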