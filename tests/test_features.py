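"""The 16-feature catalogue: worked examples, oracles, scale behaviour."""

import numpy as np
import pytest

import _oracles as orc
from facemmg import features as F
from facemmg.calibration import enumerate_pairs
from facemmg.features import (FEATURE_NAMES, FIXED_LENGTH, Standardizer,
                              build_feature_matrix)


class TestQuantile:
    def test_constant(self):
        assert F.quantile(np.full(7, 3.3), 0.25) == 3.3

    def test_extremes_and_interpolation(self):
        x = np.arange(1.0, 11.0)
        assert F.quantile(x, 1.0) == 10.0
        assert F.quantile(x, 0.0) == 1.0
        # linear interpolation at rank 0.9: between 1 and 2
        assert F.quantile(x, 0.1) == pytest.approx(1.9)

    def test_monotone_in_q(self, rng):
        x = rng.normal(size=50)
        qs = np.linspace(0, 1, 21)
        vals = [F.quantile(x, q) for q in qs]
        assert np.all(np.diff(vals) >= 0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            F.quantile(np.array([]), 0.5)


class TestFFTCoefficient:
    def test_zero_signal(self):
        x = np.zeros(512)
        for k in (0, 20, 94, 256):
            assert F.abs_fft_coefficient(x, k) == 0.0

    def test_constant_is_dc_only(self):
        x = np.full(512, 2.5)
        assert F.abs_fft_coefficient(x, 0) == pytest.approx(512 * 2.5)
        assert F.abs_fft_coefficient(x, 20) == pytest.approx(0.0, abs=1e-9)

    def test_bin_aligned_cosine(self):
        n = 512
        x = np.cos(2 * np.pi * 20 * np.arange(n) / n)
        assert F.abs_fft_coefficient(x, 20) == pytest.approx(n / 2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            F.abs_fft_coefficient(np.zeros(512), 257)


class TestLinearTrend:
    def test_exact_fit(self):
        x = 3.0 * np.arange(50) - 7.0
        slope, p, stderr, r = F.linear_trend(x)
        assert slope == pytest.approx(3.0)
        assert stderr == pytest.approx(0.0, abs=1e-12)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(0.0, abs=1e-12)

    def test_constant_conventions(self):
        slope, p, stderr, r = F.linear_trend(np.full(30, 4.2))
        assert (slope, p, stderr, r) == (0.0, 1.0, 0.0, 0.0)

    def test_matches_reference_ols(self, rng):
        import statsmodels.api as sm
        x = rng.normal(size=200)
        t = sm.add_constant(np.arange(200.0))
        fit = sm.OLS(x, t).fit()
        _, p, stderr, _ = F.linear_trend(x)
        assert p == pytest.approx(fit.pvalues[1], abs=1e-10)
        assert stderr == pytest.approx(fit.bse[1], abs=1e-10)


class TestEnergyRatio:
    def test_uniform_energy(self):
        x = np.full(100, 2.0)
        for focus in (1, 5, 8, 10):
            assert F.energy_ratio_by_chunks(x, 10, focus) == pytest.approx(0.1)

    def test_energy_localized_in_first_tenth(self):
        x = np.zeros(200)
        x[:20] = 3.0
        assert F.energy_ratio_by_chunks(x, 10, 1) == pytest.approx(1.0)
        assert F.energy_ratio_by_chunks(x, 10, 8) == 0.0

    def test_ratios_sum_to_one_and_match_oracle(self, rng):
        x = rng.normal(size=173)  # deliberately not divisible by 10
        ratios = [F.energy_ratio_by_chunks(x, 10, k) for k in range(1, 11)]
        assert sum(ratios) == pytest.approx(1.0)
        for k in range(1, 11):
            assert ratios[k - 1] == pytest.approx(
                orc.energy_ratio_loop(x, 10, k), rel=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            F.energy_ratio_by_chunks(np.zeros(100), 10, 1)


class TestAutocorrelation:
    def test_hand_computed_value(self):
        assert F.autocorrelation(np.arange(1.0, 6.0), 2) == pytest.approx(-1 / 6)

    def test_periodic_limit(self):
        x = np.tile([1.0, -1.0], 2000)
        assert F.autocorrelation(x, 2) == pytest.approx(1.0, abs=1e-3)

    def test_constant_is_zero_by_convention(self):
        assert F.autocorrelation(np.full(20, 5.0), 2) == 0.0


class TestC3:
    def test_zeros_and_constant(self):
        assert F.c3(np.zeros(20), 3) == 0.0
        assert F.c3(np.full(20, 2.0), 3) == pytest.approx(2.0 ** 4)

    def test_hand_computed_value(self):
        assert F.c3(np.arange(1.0, 8.0), 1) == pytest.approx(520.8)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            F.c3(np.arange(6.0), 3)


class TestCountBelowMean:
    def test_examples(self):
        assert F.count_below_mean(np.array([1.0, 2.0, 3.0])) == 1
        assert F.count_below_mean(np.full(9, 7.0)) == 0


class TestAggTrendMinRValue:
    def test_monotone_ramps(self):
        n = 60
        assert F.agg_linear_trend_min_rvalue(np.arange(float(n)), 10) \
            == pytest.approx(1.0)
        assert F.agg_linear_trend_min_rvalue(-np.arange(float(n)), 10) \
            == pytest.approx(-1.0)

    def test_composes_chunk_min_with_trend(self, rng):
        x = rng.normal(size=107)
        mins = [min(x[i * 10:(i + 1) * 10]) for i in range(10)]
        expected = F.linear_trend(np.array(mins))[3]
        assert F.agg_linear_trend_min_rvalue(x, 10) == pytest.approx(expected)

    def test_alternative_reading_available(self, rng):
        x = rng.normal(size=50)
        per_chunk = min(F.linear_trend(x[i * 10:(i + 1) * 10])[3]
                        for i in range(5))
        assert F.agg_linear_trend_min_rvalue(x, 10, mode="per_chunk") \
            == pytest.approx(per_chunk)

    def test_too_few_chunks_rejected(self):
        with pytest.raises(ValueError):
            F.agg_linear_trend_min_rvalue(np.arange(15.0), 10)


class TestLangevinFixedPoint:
    def test_recovers_ou_attractor(self):
        for seed in (0, 1, 2):
            x = orc.simulate_ou(seed, n=10000, mu=3.0)
            assert abs(F.max_langevin_fixed_point(x) - 3.0) <= 0.3

    def test_recovers_largest_bistable_fixed_point(self):
        x = orc.simulate_bistable(0)
        assert abs(F.max_langevin_fixed_point(x) - 1.0) <= 0.2

    def test_constant_series_is_nan(self):
        assert np.isnan(F.max_langevin_fixed_point(np.full(200, 1.0)))


class TestRatioBeyondSigma:
    def test_examples(self):
        assert F.ratio_beyond_r_sigma(np.full(10, 3.0)) == 0.0
        assert F.ratio_beyond_r_sigma(np.tile([1.0, -1.0], 10)) == 0.0
        assert F.ratio_beyond_r_sigma(np.array([0, 0, 0, 0, 10.0])) \
            == pytest.approx(0.2)


class TestMeanAbsChange:
    def test_examples(self):
        assert F.mean_abs_change_quantiles(np.array([1.0, 3.0, 2.0])) \
            == pytest.approx(1.5)
        assert F.mean_abs_change_quantiles(np.full(10, 2.0)) == 0.0
        ramp = 5.0 + 0.25 * np.arange(30)
        assert F.mean_abs_change_quantiles(ramp) == pytest.approx(0.25)

    def test_corridor_restricts_pairs(self):
        x = np.array([0.0, 1.0, 100.0, 1.0, 2.0])
        # corridor excludes the spike; only (0,1) and (1,2) pairs remain
        val = F.mean_abs_change_quantiles(x, qL=0.0, qH=0.6)
        assert val == pytest.approx(1.0)


def test_every_feature_matches_its_oracle_on_random_vectors():
    """Each catalogue feature equals an independent brute-force computation."""
    rng = np.random.default_rng(2024)
    for trial in range(200):
        n = int(rng.integers(60, 140))
        x = rng.normal(scale=rng.uniform(0.5, 50), size=n)
        assert F.autocorrelation(x, 2) == pytest.approx(
            orc.autocorrelation_loop(x, 2), rel=1e-9, abs=1e-12)
        assert F.c3(x, 3) == pytest.approx(
            orc.c3_loop(x, 3), rel=1e-9, abs=1e-9)
        assert F.count_below_mean(x) == orc.count_below_mean_loop(x)
        assert F.ratio_beyond_r_sigma(x, 1.5) == pytest.approx(
            orc.ratio_beyond_loop(x, 1.5), abs=1e-12)
        assert F.mean_abs_change_quantiles(x) == pytest.approx(
            orc.mean_abs_change_loop(x), rel=1e-9)
        k = int(rng.integers(0, n // 2 + 1))
        assert F.abs_fft_coefficient(x, k) == pytest.approx(
            abs(orc.dft_coefficient(x, k)), rel=1e-8, abs=1e-8)


def test_scale_behaviour():
    """Homogeneity/invariance of the features under x -> a*x (a > 0)."""
    rng = np.random.default_rng(99)
    for _ in range(20):
        x = rng.normal(size=120)
        a = float(rng.uniform(0.1, 10))
        # degree-1 homogeneous
        assert F.quantile(a * x, 0.8) == pytest.approx(a * F.quantile(x, 0.8))
        assert F.quantile(a * x, 0.1) == pytest.approx(a * F.quantile(x, 0.1))
        assert F.linear_trend(a * x)[2] == pytest.approx(
            a * F.linear_trend(x)[2])
        assert F.mean_abs_change_quantiles(a * x) == pytest.approx(
            a * F.mean_abs_change_quantiles(x))
        # scale-invariant
        assert F.autocorrelation(a * x, 2) == pytest.approx(
            F.autocorrelation(x, 2))
        assert F.agg_linear_trend_min_rvalue(a * x, 10) == pytest.approx(
            F.agg_linear_trend_min_rvalue(x, 10))
        assert F.ratio_beyond_r_sigma(a * x, 1.5) == pytest.approx(
            F.ratio_beyond_r_sigma(x, 1.5))
        # quartic
        assert F.c3(a * x, 3) == pytest.approx(a ** 4 * F.c3(x, 3), rel=1e-9)


class TestPrepare:
    def test_pads_to_fixed_length_and_removes_mean(self, rng):
        x = rng.normal(loc=5.0, size=430)
        p = F.prepare(x)
        assert p.size == FIXED_LENGTH
        assert p[430:].sum() == 0.0
        assert abs(x.mean() + p[:430].mean() - x.mean()) < 1e-9

    def test_truncates_overlong(self, rng):
        assert F.prepare(rng.normal(size=600)).size == FIXED_LENGTH


class TestStandardizer:
    def test_training_columns_standardized(self, rng):
        X = rng.normal(loc=3, scale=7, size=(40, 5))
        std = Standardizer().fit(X)
        Z = std.transform(X)
        assert np.all(np.abs(Z.mean(axis=0)) < 1e-8)
        assert np.allclose(Z.std(axis=0), 1.0)

    def test_nan_imputed_with_training_median(self):
        X = np.array([[1.0], [2.0], [3.0], [np.nan]])
        std = Standardizer().fit(X)
        assert std.medians[0] == 2.0
        Z = std.transform(np.array([[np.nan]]))
        # imputed value equals the median, standardized
        assert Z[0, 0] == pytest.approx((2.0 - std.means[0]) / std.sds[0])

    def test_fit_is_training_rows_only(self, rng):
        X = rng.normal(size=(30, 3))
        std = Standardizer().fit(X[:20])
        Z = std.transform(X)
        assert np.all(np.abs(Z[:20].mean(axis=0)) < 1e-8)
        assert not np.all(np.abs(Z.mean(axis=0)) < 1e-8)


class TestFeatureMatrix:
    def test_all_pairs_yield_176_columns(self, small_feature_matrix):
        fm = small_feature_matrix
        assert fm.n_columns == 11 * 16 == 176
        assert fm.values.shape[0] == len(fm.labels)
        assert list(fm.values.columns[:16]) == [
            f"temple_L-temple_R__{name}" for name in FEATURE_NAMES]

    def test_subset_yields_96_columns(self, small_separable_dataset,
                                      small_tables):
        fm = build_feature_matrix(
            small_separable_dataset, enumerate_pairs("eyebrows_cheeks"),
            small_tables)
        assert fm.n_columns == 6 * 16 == 96

    def test_identical_events_give_identical_rows(self, small_separable_dataset,
                                                  small_tables):
        import copy
        ds = copy.copy(small_separable_dataset)
        ev = ds.events[0]
        twin = type(ev)(samples=ev.samples.copy(), fs=ev.fs,
                        subject_id=ev.subject_id, session_id=ev.session_id,
                        gesture=ev.gesture, repetition=99, event_id="twin")
        ds.events = [ev, twin]
        fm = build_feature_matrix(ds, enumerate_pairs("all"), small_tables)
        assert np.array_equal(fm.values.iloc[0].to_numpy(),
                              fm.values.iloc[1].to_numpy())
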