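"""Compilation preprocessing, fPIC conversion, zero-truncated KDE,
skewness, and the basin-statistics pipeline."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import pelacarb as pc
from pelacarb.skewed import (
    TruncatedKDE,
    maredat_pipeline,
    preprocess,
    silverman_bandwidth,
)


def _records(values, depths=None):
    values = np.asarray(values, dtype=float)
    depths = np.full(values.size, 100.0) if depths is None else np.asarray(depths)
    return pd.DataFrame({"depth": depths, "carbon_biomass": values})


def _brute_force_3sigma(values, k=3.0):
    """Independent oracle: plain-Python mean/sd and clipping."""
    n = len(values)
    mean = sum(values) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))
    return [v for v in values if abs(v - mean) <= k * sd]


class TestPreprocess:
    def test_small_sample_outlier_cannot_be_removed(self):
        """At n=5 the max standardised deviation is (n-1)/sqrt(n) < 3,
        so the 3-sigma rule keeps even a huge value."""
        res = preprocess(_records([0, 1, 2, 3, 1000]))
        assert res.n_outliers_removed == 0 and res.n_used == 5

    def test_outlier_removal_matches_brute_force(self):
        vals = [0.0] * 7 + [1.0] * 92 + [500.0]
        expected = _brute_force_3sigma(vals)
        res = preprocess(_records(vals))
        assert sorted(res.values) == pytest.approx(sorted(expected))
        assert res.n_outliers_removed == len(vals) - len(expected) == 1
        assert res.n_zeros == 7

    def test_single_pass_not_iterated(self):
        """A second-tier outlier that only becomes extreme after the
        first removal is retained (single-shot rule)."""
        vals = [1.0] * 200 + [50.0, 5000.0]
        first = _brute_force_3sigma(vals)
        assert 50.0 in first  # sd inflated by 5000 keeps 50 in pass one
        res = preprocess(_records(vals))
        assert 50.0 in res.values

    def test_all_zeros_retained_no_removals(self):
        res = preprocess(_records([0.0] * 20))
        assert res.n_used == 20 and res.n_outliers_removed == 0

    def test_depth_boundary_inclusive(self):
        res = preprocess(_records([1.0, 2.0, 3.0], depths=[250.0, 251.0, 100.0]))
        assert res.n_depth_excluded == 1 and res.n_used == 2

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            preprocess(_records([]))


class TestCarbonToCaCO3:
    def test_degenerate_ratio_closed_form(self, rng):
        r = 0.27 / 0.73
        out = pc.carbon_to_caco3_mc(np.array([1.0]), (r, r), 10, rng)
        assert np.allclose(out, 0.27 * 8.33)  # 2.249 mg m-3

    def test_zero_carbon_is_zero_everywhere(self, rng):
        out = pc.carbon_to_caco3_mc(np.array([0.0, 0.0]), (0.2, 0.56), 50, rng)
        assert np.all(out == 0.0)

    def test_fpic_support_from_ratio_endpoints(self, rng):
        out = pc.carbon_to_caco3_mc(np.array([1.0]), (0.20, 0.56), 100_000, rng)
        fpic = out / 8.33
        assert fpic.min() >= 0.20 / 1.20 - 1e-9
        assert fpic.max() <= 0.56 / 1.56 + 1e-9

    def test_layer_integration(self):
        assert pc.layer_integrate(0.5) == pytest.approx(125.0)
        assert pc.layer_integrate(0.0) == 0.0
        assert pc.layer_integrate(0.5, 1000.0) == pytest.approx(500.0)


class TestTruncatedKDE:
    def test_density_integrates_to_one_on_half_line(self, rng):
        values = np.abs(rng.lognormal(0, 1.3, size=400))
        values[:30] = 0.0  # zeros up-weighted, not lost
        kde = TruncatedKDE(values)
        grid = np.linspace(0, values.max() + 10 * kde.bandwidth, 20000)
        integral = np.trapezoid(kde.pdf(grid), grid)
        assert integral == pytest.approx(1.0, abs=1e-6)

    def test_cdf_reaches_one(self, rng):
        values = rng.exponential(2.0, size=200)
        kde = TruncatedKDE(values)
        assert kde.cdf([values.max() + 12 * kde.bandwidth])[0] == pytest.approx(1.0, abs=1e-9)

    def test_point_mass_degenerate_sample(self):
        s = pc.truncated_kde(np.full(100, 7.0))
        assert s.p50 == s.mode == 7.0
        assert s.p32 == s.p68 == 7.0

    def test_lognormal_median_recovery(self):
        rng = np.random.default_rng(42)
        values = rng.lognormal(0.0, 1.0, size=10_000)
        s = pc.truncated_kde(values)
        assert s.p50 == pytest.approx(1.0, rel=0.05)
        assert s.p32 <= s.p50 <= s.p68

    def test_needs_at_least_five_values(self):
        with pytest.raises(ValueError):
            pc.truncated_kde(np.ones(4))

    def test_zero_heavy_sample_mode_near_zero(self, rng):
        values = np.concatenate([np.zeros(300), rng.exponential(0.05, 100)])
        s = pc.truncated_kde(values)
        assert s.mode < np.quantile(values, 0.9)
        assert s.n_zeros == 300


class TestSampleSkewness:
    def test_symmetric_sample_is_zero(self):
        assert pc.sample_skewness([0.0, 1.0, 2.0]) == pytest.approx(0.0, abs=1e-12)

    def test_three_zeros_one_one(self):
        # brute-force moment oracle: m2=0.1875, m3=0.09375 -> 2/sqrt(3)
        assert pc.sample_skewness([0, 0, 0, 1]) == pytest.approx(2 / math.sqrt(3), rel=1e-9)

    def test_zero_variance_is_nan(self):
        assert math.isnan(pc.sample_skewness([2.0, 2.0, 2.0]))

    def test_bias_corrected_variant_larger_for_small_n(self):
        g1 = pc.sample_skewness([0, 0, 0, 1])
        G1 = pc.sample_skewness([0, 0, 0, 1], bias_corrected=True)
        assert G1 > g1


class TestMaredatPipeline:
    def test_degenerate_priors_collapse_to_closed_form(self):
        """Fixed fPIC = 0.27 and fixed turnover reduce the stochastic
        pipeline to biomass x 250 x 0.27 x 8.33 / tau exactly."""
        vals = np.array([0.0, 0.1, 0.5, 1.0, 2.0, 0.3, 0.7])
        r = 0.27 / 0.73
        res = maredat_pipeline(_records(vals), pic_poc_range=(r, r),
                               turnover_range=(10.0, 10.0), n_boot=0, n_mc=3, seed=1)
        expected = np.sort(vals) * 250 * 0.27 * 8.33 / 10.0
        got = np.sort(np.unique(np.round(res.samples["production"], 12)))
        assert got == pytest.approx(np.sort(np.unique(np.round(expected, 12))))

    def test_single_bootstrap_reduces_to_single_pass(self):
        vals = np.linspace(0.1, 2.0, 30)
        res = maredat_pipeline(_records(vals), n_boot=1, n_mc=5, seed=3)
        assert res.boot_ci == {}
        assert res.biomass.n_used > 0

    def test_unit_rescaling_equivariance(self):
        """Multiplying all biomass by c multiplies all percentiles by c."""
        rng = np.random.default_rng(7)
        vals = rng.lognormal(-1, 1, size=300)
        a = maredat_pipeline(_records(vals), n_boot=0, n_mc=20, seed=5)
        b = maredat_pipeline(_records(vals * 10), n_boot=0, n_mc=20, seed=5)
        for stat in ("biomass", "stock", "production"):
            sa, sb = getattr(a, stat), getattr(b, stat)
            assert sb.p50 == pytest.approx(10 * sa.p50, rel=0.02)
            assert sb.p32 == pytest.approx(10 * sa.p32, rel=0.05)

    def test_recovers_generator_truth_median(self, survey_cfg):
        df, truth = pc.gen_maredat_like(survey_cfg)
        df = df.rename(columns={"carbon_biomass": "carbon_biomass"})
        res = maredat_pipeline(df[["depth", "carbon_biomass"]], n_boot=100, n_mc=60, seed=13)
        lo, hi = res.boot_ci["biomass"]
        target = truth["caco3_median_marginal"]
        # KDE p50 close to the analytic marginal median, and the
        # bootstrap CI of the median brackets it
        assert res.biomass.p50 == pytest.approx(target, rel=0.12)
        assert lo * 0.8 < target < hi * 1.2

    def test_bootstrap_ci_calibration(self):
        """Bootstrap 95% CIs of the median cover the analytic median at
        roughly the nominal rate (pure lognormal, no zeros)."""
        cover = 0
        reps = 60
        r_fix = (0.27 / 0.73, 0.27 / 0.73)
        for i in range(reps):
            rng = np.random.default_rng(1000 + i)
            vals = rng.lognormal(0.0, 1.0, size=150)
            res = maredat_pipeline(_records(vals), pic_poc_range=r_fix,
                                   turnover_range=(10.0, 10.0),
                                   n_boot=150, n_mc=2, seed=i)
            lo, hi = res.boot_ci["biomass"]
            true_median = 1.0 * 0.27 * 8.33
            cover += lo <= true_median <= hi
        assert cover / reps >= 0.80  # ~95% nominal, allow MC slack


@given(st.lists(st.one_of(st.just(0.0), st.floats(0.01, 10.0)), min_size=5, max_size=40))
@settings(max_examples=50, deadline=None)
def test_truncated_density_nonnegative_and_normalized(values):
    values = np.asarray(values)
    if np.all(values == values[0]):
        return
    kde = TruncatedKDE(values)
    if kde.degenerate:
        return
    xmax = values.max() + 10 * kde.bandwidth
    npts = int(min(50_000, max(5_000, 10 * xmax / kde.bandwidth)))
    grid = np.linspace(0, xmax, npts)
    dens = kde.pdf(grid)
    assert np.all(dens >= 0)
    assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-4)


def test_silverman_bandwidth_positive_scaling(rng):
    v = rng.lognormal(0, 1, 500)
    h = silverman_bandwidth(v)
    assert h > 0
    assert silverman_bandwidth(v * 10) == pytest.approx(10 * h, rel=1e-9)
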