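"""Chi-square/G/size-structure statistics and diel activity profiles."""

import math

import numpy as np
import pytest
from scipy import stats

from trophon import (
    GroupKey,
    activity_profile,
    chisq_uniform,
    class_histogram,
    day_night_test,
    g_test,
    interval_test,
    seasonal_occurrence_gtest,
    sex_ratio_test,
    size_structure_compare,
)
from trophon.core_data import INTERVALS, NOCTURNAL_INTERVALS

from conftest import make_specimen


class TestChisqUniform:
    def test_near_even_sex_ratio(self):
        res = chisq_uniform([177, 164])
        assert res.statistic == pytest.approx(0.4956, abs=5e-4)
        assert res.df == 1
        assert res.p_value > 0.05

    def test_biased_sex_ratio_with_yates(self):
        res = chisq_uniform([39, 22], yates=True)
        assert res.statistic == pytest.approx(4.7377, abs=5e-4)
        assert res.corrected_statistic == pytest.approx(4.1967, abs=5e-4)
        assert res.corrected_statistic < res.statistic
        assert res.p_value < 0.05

    def test_equal_counts_give_zero(self):
        res = chisq_uniform([10, 10])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_yates_requires_two_cells(self):
        with pytest.raises(ValueError, match="k = 2"):
            chisq_uniform([5, 5, 5], yates=True)

    def test_matches_scipy_on_random_counts(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            k = int(rng.integers(2, 9))
            counts = rng.integers(1, 500, k)
            res = chisq_uniform(counts)
            ref_stat, ref_p = stats.chisquare(counts)
            assert res.statistic == pytest.approx(float(ref_stat), rel=1e-12)
            assert res.p_value == pytest.approx(float(ref_p), rel=1e-9)

    def test_yates_never_exceeds_uncorrected(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            counts = rng.integers(0, 300, 2)
            if counts.sum() == 0:
                continue
            res = chisq_uniform(counts, yates=True)
            assert res.corrected_statistic <= res.statistic + 1e-12

    def test_type_one_error_calibration(self):
        # k = 8 intervals, n = 341 multinomial draws under uniformity
        rng = np.random.default_rng(2024)
        draws = rng.multinomial(341, [1 / 8] * 8, size=2000)
        exp = 341 / 8
        stat = ((draws - exp) ** 2 / exp).sum(axis=1)
        rejections = float(np.mean(stats.chi2.sf(stat, 7) < 0.05))
        assert 0.03 <= rejections <= 0.07


class TestDayNightTest:
    def _profile(self, counts):
        specimens = []
        k = 0
        for interval, n in zip(INTERVALS, counts):
            for _ in range(n):
                k += 1
                specimens.append(make_specimen(f"S{k}", interval=interval))
        return activity_profile(specimens, GroupKey("S. gibbus"))

    def test_uniform_per_interval_rate_gives_zero(self):
        profile = self._profile([10] * 8)
        res = day_night_test(profile)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_all_nocturnal_is_significant(self):
        profile = self._profile([20, 20, 20, 20, 20, 0, 0, 0])
        res = day_night_test(profile)
        assert res.p_value < 0.05

    def test_equal_expectation_flag(self):
        profile = self._profile([10] * 8)
        res = day_night_test(profile, expectation="equal")
        # 50 night vs 30 day is far from 50/50
        assert res.statistic == pytest.approx((50 - 40) ** 2 / 40 * 2, rel=1e-12)

    def test_invariant_to_which_intervals_are_nocturnal(self):
        # same per-interval counts assigned to a different 5/3 labelling
        counts = [12, 7, 9, 14, 6, 11, 8, 13]
        profile = self._profile(counts)
        night = sum(
            c for i, c in zip(INTERVALS, counts) if i in NOCTURNAL_INTERVALS
        )
        day = sum(counts) - night
        direct = chisq_uniform([night, day], expected=[5, 3])
        assert day_night_test(profile).statistic == pytest.approx(
            direct.statistic, rel=1e-12
        )


class TestGTest:
    def test_independent_table_gives_zero(self):
        assert g_test([[10, 20], [20, 40]]).statistic == pytest.approx(0.0, abs=1e-12)

    def test_diagonal_table(self):
        res = g_test([[10, 0], [0, 10]])
        # hand evaluation of 2 * sum O ln(O/E) with E = 5 everywhere
        assert res.statistic == pytest.approx(40 * math.log(2), rel=1e-12)
        assert res.statistic == pytest.approx(27.726, abs=5e-4)
        assert res.df == 1

    def test_matches_scipy_log_likelihood(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            shape = (2, int(rng.integers(2, 6)))
            table = rng.integers(1, 200, shape)
            res = g_test(table)
            ref = stats.chi2_contingency(table, correction=False,
                                         lambda_="log-likelihood")
            assert res.statistic == pytest.approx(float(ref.statistic), rel=1e-10)
            assert res.p_value == pytest.approx(float(ref.pvalue), rel=1e-9)

    def test_williams_correction_shrinks_g(self):
        res = g_test([[12, 3], [5, 9]], williams=True)
        assert res.corrected_statistic < res.statistic

    def test_structural_zero_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            g_test([[0, 0], [5, 9]])

    def test_null_distribution_is_approximately_chisquare(self):
        # G on independently drawn margins-free tables ~ chi2(df)
        rng = np.random.default_rng(4)
        samples = []
        for _ in range(1000):
            table = rng.multinomial(400, [1 / 6] * 6).reshape(2, 3)
            samples.append(g_test(table).statistic)
        quantiles = np.quantile(samples, [0.25, 0.5, 0.75, 0.9])
        expected = stats.chi2.ppf([0.25, 0.5, 0.75, 0.9], 2)
        assert np.allclose(quantiles, expected, rtol=0.15)

    def test_seasonal_occurrence_table(self, preset_dataset):
        specimens, items = preset_dataset
        res = seasonal_occurrence_gtest(items, specimens, "S. gibbus", "fish")
        assert res.df == 1
        assert 0.0 <= res.p_value <= 1.0


class TestSexRatio:
    def test_undetermined_excluded(self):
        specimens = [
            make_specimen("S1", sex="male"),
            make_specimen("S2", sex="female"),
            make_specimen("S3", sex="undetermined"),
        ]
        res = sex_ratio_test(specimens, GroupKey("S. gibbus"))
        assert res.statistic == 0.0


class TestSizeStructure:
    def test_identical_samples_give_t_zero(self):
        a = [10.0, 12.0, 11.0, 13.0, 9.0]
        out = size_structure_compare(a, list(a))
        assert out["t"].statistic == pytest.approx(0.0, abs=1e-12)

    def test_shifted_normals_detected(self):
        rng = np.random.default_rng(5)
        hits = 0
        for _ in range(200):
            a = rng.normal(100.0, 10.0, 50)
            b = rng.normal(120.0, 10.0, 50)  # shift of two standard deviations
            hits += size_structure_compare(a, b)["t"].p_value < 0.05
        assert hits >= 198

    def test_heteroscedastic_inputs_flagged(self):
        rng = np.random.default_rng(6)
        a = rng.normal(100.0, 1.0, 60)
        b = rng.normal(100.0, 12.0, 60)
        out = size_structure_compare(a, b)
        assert out["bartlett"].p_value < 0.05
        assert "heteroscedastic" in out["t"].flags

    def test_zero_variance_sample_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            size_structure_compare([5.0, 5.0, 5.0], [1.0, 2.0, 3.0])


class TestClassHistogram:
    def test_unit_width_classes(self):
        out = class_histogram([1.0, 1.5, 2.0], 1.0)
        assert out == {(1.0, 2.0): 2, (2.0, 3.0): 1}

    def test_counts_conserved(self):
        rng = np.random.default_rng(7)
        values = rng.normal(50, 20, 500)
        out = class_histogram(values, 5.0)
        assert sum(out.values()) == 500

    def test_empty_sample(self):
        assert class_histogram([], 2.0) == {}

    def test_invalid_width(self):
        with pytest.raises(ValueError):
            class_histogram([1.0], 0.0)


class TestActivityProfile:
    def test_counts_and_day_night_split(self, preset_dataset):
        specimens, _ = preset_dataset
        profile = activity_profile(specimens, GroupKey("S. rhombeus"))
        total = sum(profile.counts.values())
        assert profile.night_count + profile.day_count == total
        assert sum(profile.rel_freq.values()) == pytest.approx(1.0)
        assert interval_test(profile).df == 7
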