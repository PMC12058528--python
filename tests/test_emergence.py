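"""Bootstrap baseline, ULE thresholds, emergence tallies and ensemble tests."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from conftest import make_field
from ulex import emergence as emg
from ulex.util import nearest_rank_percentile


def controls_from(values_by_run, year0=1700):
    return {rid: make_field(v, year0=year0) for rid, v in values_by_run.items()}


def flat_mask(nlat, nlon, country=0):
    return xr.DataArray(
        np.full((nlat, nlon), country, dtype=np.int32), dims=("lat", "lon"),
        coords={"lat": 0.5 * np.arange(nlat), "lon": 0.5 * np.arange(nlon)})


class TestBootstrap:
    def test_pooled_size_is_runs_times_nboot(self):
        rng = np.random.default_rng(0)
        ctls = controls_from({f"r{i}": rng.random((250, 1, 2)) for i in range(4)})
        s = emg.bootstrap_preindustrial(ctls, flat_mask(1, 2), {0: 60.0},
                                        n_boot=500, seed=1, min_control_years=239)
        assert s.size == 4 * 500
        assert s.n_runs == 4

    def test_zero_control_gives_zero_exposures(self):
        ctls = controls_from({"r0": np.zeros((250, 1, 1))})
        s = emg.bootstrap_preindustrial(ctls, flat_mask(1, 1), {0: 42.5},
                                        n_boot=200, seed=1)
        assert (s.samples == 0).all()
        assert s.threshold(99.99).item() == 0.0

    def test_resampling_mean_identity(self):
        """Bootstrap mean approximates L times the realized control rate."""
        rng = np.random.default_rng(2)
        ctl = (rng.random((639, 1, 1)) < 0.01).astype(float)
        p_hat = ctl.mean()
        s = emg.bootstrap_preindustrial(controls_from({"r0": ctl}), flat_mask(1, 1),
                                        {0: 60.0}, n_boot=10_000, seed=3)
        want = 60.0 * p_hat
        se = np.sqrt(60.0 * p_hat * (1 - p_hat) / 10_000)
        assert abs(s.samples.mean() - want) <= 3 * se

    def test_short_control_is_an_error(self):
        ctls = controls_from({"r0": np.zeros((100, 1, 1))})
        with pytest.raises(ValueError, match="239"):
            emg.bootstrap_preindustrial(ctls, flat_mask(1, 1), {0: 60.0}, n_boot=10)

    def test_missing_country_le_is_an_error(self):
        ctls = controls_from({"r0": np.zeros((250, 1, 1))})
        with pytest.raises(ValueError, match="life expectancy"):
            emg.bootstrap_preindustrial(ctls, flat_mask(1, 1), {5: 60.0}, n_boot=10)

    def test_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(4)
        ctl = rng.random((250, 2, 2))
        a = emg.bootstrap_preindustrial(controls_from({"r0": ctl}), flat_mask(2, 2),
                                        {0: 50.3}, n_boot=100, seed=9)
        b = emg.bootstrap_preindustrial(controls_from({"r0": ctl}), flat_mask(2, 2),
                                        {0: 50.3}, n_boot=100, seed=9)
        np.testing.assert_array_equal(a.samples, b.samples)


class TestThresholdAndDetection:
    def test_threshold_is_a_sample_element(self):
        rng = np.random.default_rng(1)
        sample = rng.integers(0, 8, size=(5000, 4)).astype(float)
        thr = emg.ule_threshold(sample, 99.99)
        for j in range(4):
            assert thr[j] in sample[:, j]

    def test_equal_exposure_does_not_emerge(self):
        e = xr.DataArray([[3.0]], dims=("lat", "lon"))
        t = xr.DataArray([[3.0]], dims=("lat", "lon"))
        assert not bool(emg.detect_emergence(e, t).item())

    def test_zero_threshold_any_exposure_emerges(self):
        e = xr.DataArray([[0.01]], dims=("lat", "lon"))
        t = xr.DataArray([[0.0]], dims=("lat", "lon"))
        assert bool(emg.detect_emergence(e, t).item())

    def test_age_of_emergence_is_first_crossing(self):
        traj = xr.DataArray(
            np.array([[[0.0]], [[1.0]], [[2.5]], [[4.0]]]),
            dims=("age", "lat", "lon"), coords={"age": [0, 1, 2, 3]})
        t = xr.DataArray([[2.0]], dims=("lat", "lon"))
        assert emg.age_of_emergence(traj, t).item() == 2
        t9 = xr.DataArray([[9.0]], dims=("lat", "lon"))
        assert np.isnan(emg.age_of_emergence(traj, t9).item())

    def test_percentile_sensitivity_levels_off_beyond_9999(self):
        """On integer-valued samples at the study's largest pooled size,
        T at 99.99 and 99.999 differ by <= 1 event in >= 95% of cells."""
        rng = np.random.default_rng(6)
        sample = rng.binomial(60, 0.01, size=(310_000, 100)).astype(float)
        t1 = emg.ule_threshold(sample, 99.99)
        t2 = emg.ule_threshold(sample, 99.999)
        assert np.mean(np.abs(t2 - t1) <= 1.0) >= 0.95


class TestTallyAndCF:
    def test_tally_extremes_and_arithmetic(self):
        mask = flat_mask(1, 2)
        b = xr.DataArray([[100.0, 200.0]], dims=("lat", "lon"),
                         coords={"lat": mask.lat, "lon": mask.lon})
        none = xr.zeros_like(b).astype(bool)
        allc = xr.ones_like(b).astype(bool)
        first = xr.DataArray([[True, False]], dims=("lat", "lon"),
                             coords={"lat": mask.lat, "lon": mask.lon})
        assert emg.tally_emerged(none, b, mask)[0] == 0.0
        assert emg.tally_emerged(allc, b, mask)[0] == 300.0
        assert emg.tally_emerged(first, b, mask)[0] == 100.0

    def test_country_counts_sum_to_global(self, small_world, small_demography):
        ensemble, demog, _ = small_world
        cd = small_demography
        rng = np.random.default_rng(0)
        emerged = xr.DataArray(rng.random((6, 6)) < 0.4, dims=("lat", "lon"),
                               coords={"lat": demog["mask"].lat,
                                       "lon": demog["mask"].lon})
        b = xr.DataArray(rng.random((6, 6)) * 1000, dims=("lat", "lon"),
                         coords={"lat": demog["mask"].lat, "lon": demog["mask"].lon})
        total, per_country = emg.tally_emerged(emerged, b, demog["mask"])
        assert per_country.sum() == pytest.approx(total, rel=1e-12)

    def test_cf_bounds_and_undefined_totals(self):
        assert emg.cohort_fraction(50.0, 100.0) == pytest.approx(0.5)
        assert emg.cohort_fraction(0.0, 100.0) == 0.0
        assert np.isnan(emg.cohort_fraction(0.0, 0.0))

    def test_full_emergence_gives_unit_cf_zero_spread(self):
        per_run = pd.DataFrame({
            "birth_year": [2000] * 3, "pathway": [1.5] * 3,
            "run": list("abc"), "cf": [1.0, 1.0, 1.0]})
        stats = emg.ensemble_cf_stats(per_run)
        row = stats.iloc[0]
        assert row.cf_mean == row.cf_min == row.cf_max == 1.0
        assert row.n_runs == 3


class TestRegionRestriction:
    def test_global_hazard_leaves_cf_unchanged(self):
        rng = np.random.default_rng(0)
        field = make_field(rng.random((10, 2, 2)) + 0.1)
        region = emg.restrict_to_exposed_regions([field])
        assert bool(region.all())

    def test_confined_hazard_halves_denominator(self):
        vals = np.zeros((5, 1, 2))
        vals[:, 0, 0] = 0.5                         # only first cell ever exposed
        field = make_field(vals)
        region = emg.restrict_to_exposed_regions([field])
        b = xr.DataArray([[100.0, 100.0]], dims=("lat", "lon"),
                         coords={"lat": field.lat, "lon": field.lon})
        emerged = xr.DataArray([[True, False]], dims=("lat", "lon"),
                               coords={"lat": field.lat, "lon": field.lon})
        cf_global = emg.cohort_fraction(100.0, 200.0)
        cf_region = emg.rebased_cohort_fraction(emerged, b, region)
        assert cf_region == pytest.approx(2 * cf_global)

    def test_empty_region_is_an_error(self):
        field = make_field(np.zeros((5, 1, 1)))
        with pytest.raises(ValueError, match="denominator"):
            emg.restrict_to_exposed_regions([field])


class TestSignificance:
    def test_identical_groups_not_significant(self):
        r = emg.ensemble_significance([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert not r.significant
        assert r.method == "degenerate"

    def test_separated_constant_groups_exact_rank_p(self):
        r = emg.ensemble_significance([0.0, 0.0, 0.0, 0.0], [1.0, 1.0, 1.0, 1.0])
        assert r.significant
        assert r.method == "mannwhitney-exact"
        assert r.pvalue == pytest.approx(2 / 70, rel=1e-9)

    def test_type_i_error_near_nominal_level(self):
        """Same-distribution ensembles are rejected at about the 5% level."""
        rng = np.random.default_rng(123)
        n_rep, n = 2000, 8
        from scipy import stats as ss
        a = rng.normal(size=(n_rep, n))
        b = rng.normal(size=(n_rep, n))
        p = ss.ttest_ind(a, b, axis=1, equal_var=False).pvalue
        rate = float((p < 0.05).mean())
        assert abs(rate - 0.05) <= 0.02


def test_binomial_lifetime_quantile_matches_cdf_oracle():
    """40,000 Binomial(60, 0.01) lifetime sums: nearest-rank 99.99th pct = 5.

    The analytic CDF puts P(X <= 4) = 0.99965 < 0.9999 <= P(X <= 5) = 0.99997,
    so the threshold should land on 5.
    """
    from scipy.stats import binom
    assert binom.cdf(4, 60, 0.01) < 0.9999 <= binom.cdf(5, 60, 0.01)
    rng = np.random.default_rng(0)
    draws = rng.binomial(60, 0.01, size=40_000).astype(float)
    assert nearest_rank_percentile(draws, 99.99) == 5.0
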