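import numpy as np
import pytest
import xarray as xr
from hypothesis import HealthCheck, settings

import ulex
from ulex import demographics as demo
from ulex import synthetic as syn

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("ci")


def make_field(values, year0=2000, name="exposure"):
    """(time, lat, lon) DataArray from a nested array, years starting at year0."""
    vals = np.asarray(values, dtype=float)
    t, nlat, nlon = vals.shape
    return xr.DataArray(
        vals, dims=("time", "lat", "lon"),
        coords={"time": year0 + np.arange(t),
                "lat": 0.5 * np.arange(nlat), "lon": 0.5 * np.arange(nlon)},
        name=name,
    )


@pytest.fixture(scope="session")
def small_cfg():
    return syn.SynthConfig(
        n_lat=6, n_lon=6, n_countries=3, control_years=300,
        runs=syn.default_runs(3), master_seed=3,
    )


@pytest.fixture(scope="session")
def small_world(small_cfg):
    ensemble = syn.gen_exposure_ensemble(small_cfg)
    demog = syn.gen_demographics(small_cfg)
    vuln = syn.gen_vulnerability(small_cfg, demog["population"])
    return ensemble, demog, vuln


@pytest.fixture(scope="session")
def small_demography(small_world):
    _, demog, _ = small_world
    return demo.build_country_demography(
        demog["life_expectancy"], demog["cohort_sizes"])


@pytest.fixture(scope="session")
def recovery_run(tmp_path_factory):
    """One medium synthetic world run end-to-end, shared across acceptance tests."""
    cfg = ulex.RunConfig(
        synthetic=dict(n_lat=20, n_lon=20, n_countries=4, n_runs=4),
        pathway_step=1.0, n_boot=10_000, seed=11,
    )
    out = tmp_path_factory.mktemp("recovery")
    res = ulex.run_pipeline(cfg, out)
    scfg = cfg.synth_config()
    ensemble = syn.gen_exposure_ensemble(scfg)
    demog = syn.gen_demographics(scfg)
    cd = demo.build_country_demography(demog["life_expectancy"], demog["cohort_sizes"])
    pop = demo.extrapolate_population(demog["population"])
    birth_years = np.arange(1960, 2021)
    cohort = demo.cohort_size_at_grid(pop, cd.shares, demog["mask"], birth_years)
    return {
        "cfg": cfg, "res": res, "ensemble": ensemble, "demog": demog,
        "cd": cd, "cohort": cohort, "birth_years": birth_years,
    }
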