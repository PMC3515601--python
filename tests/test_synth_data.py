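"""The pattern-plus-noise generator."""

import numpy as np
import pytest

import spl
from spl.synth_data import AR1_COEF, noise_scale_for_tsnr


class TestPatternPair:
    def test_fixed_mode_uses_first_and_last_blocks(self):
        spec = spl.SimulationSpec(support_mode="fixed", seed=0)
        p = spl.make_pattern_pair(spec)
        np.testing.assert_array_equal(p.support1, np.arange(25))
        np.testing.assert_array_equal(p.support2, np.arange(275, 300))

    def test_random_mode_is_disjoint_and_seed_deterministic(self):
        spec = spl.SimulationSpec(support_mode="random", seed=11)
        p1, p2 = spl.make_pattern_pair(spec), spl.make_pattern_pair(spec)
        np.testing.assert_array_equal(p1.support1, p2.support1)
        np.testing.assert_array_equal(p1.support2, p2.support2)
        assert np.intersect1d(p1.support1, p1.support2).size == 0
        assert p1.support1.size == p1.support2.size == 25

    def test_tight_feature_space_is_partitioned(self):
        spec = spl.SimulationSpec(m=50, support_size=25, support_mode="random", seed=3)
        p = spl.make_pattern_pair(spec)
        np.testing.assert_array_equal(
            np.sort(np.r_[p.support1, p.support2]), np.arange(50)
        )

    def test_too_small_feature_space_rejected(self):
        with pytest.raises(ValueError):
            spl.SimulationSpec(m=40, support_size=25)


class TestColoredNoise:
    def test_columns_are_standardized(self):
        n = spl.make_colored_noise(20, 300, 0)
        np.testing.assert_allclose(n.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(n.std(axis=0, ddof=1), 1, atol=1e-12)

    def test_seeded_determinism(self):
        np.testing.assert_array_equal(
            spl.make_colored_noise(10, 5, 42), spl.make_colored_noise(10, 5, 42)
        )

    def test_positive_lag1_autocorrelation(self):
        # oracle: an AR(1) filter with coefficient a has theoretical
        # lag-1 autocorrelation a (standardization leaves it unchanged)
        n = spl.make_colored_noise(200, 1000, 9)
        r1 = np.mean(np.sum(n[1:] * n[:-1], axis=0) / np.sum(n * n, axis=0))
        assert r1 > 0
        assert abs(r1 - AR1_COEF) < 0.05

    def test_rejects_empty_dimensions(self):
        with pytest.raises(ValueError):
            spl.make_colored_noise(0, 5, 0)


class TestMakeDataset:
    def test_default_geometry_and_labels(self, study):
        _, datasets = study
        ds = datasets[0]
        assert ds.A.shape == (20, 300)
        np.testing.assert_array_equal(ds.y, np.r_[np.ones(10), -np.ones(10)])

    def test_zero_noise_rows_equal_patterns(self):
        spec = spl.SimulationSpec(noise_scale=0.0, seed=0)
        p = spl.make_pattern_pair(spec)
        ds = spl.make_dataset(p, spec)
        np.testing.assert_array_equal(ds.A[:10], np.tile(p.u1, (10, 1)))
        np.testing.assert_array_equal(ds.A[10:], np.tile(p.u2, (10, 1)))

    def test_class_mean_difference_recovers_pattern_contrast(self):
        # class-conditional means converge to u1/u2; with 10,000 rows the
        # noise on each mean entry is ~ c/100.  The bound is 4 standard
        # errors because the maximum runs over 50 feature entries
        spec = spl.SimulationSpec(rows_per_class=5000, m=50, support_size=10, seed=1)
        p = spl.make_pattern_pair(spec)
        ds = spl.make_dataset(p, spec)
        se = spec.noise_scale / np.sqrt(5000)
        diff = ds.A[ds.y > 0].mean(axis=0) - ds.A[ds.y < 0].mean(axis=0)
        assert np.all(np.abs(diff - (p.u1 - p.u2)) < 4 * np.sqrt(2) * se)

    def test_replicates_are_deterministic_and_distinct(self):
        spec = spl.SimulationSpec(seed=5, n_replicates=3)
        _, d1 = spl.make_replicates(spec)
        _, d2 = spl.make_replicates(spec)
        for a, b in zip(d1, d2):
            np.testing.assert_array_equal(a.A, b.A)
        assert not np.array_equal(d1[0].A, d1[1].A)


class TestTestSet:
    def test_geometry(self, study):
        patterns, _ = study
        ts = spl.make_test_set(patterns, 50, 1.0, seed=7)
        assert ts.A.shape == (100, 300)
        assert (ts.y == 1).sum() == 50

    def test_zero_noise_rows_are_pattern_copies(self, study):
        patterns, _ = study
        ts = spl.make_test_set(patterns, 3, 0.0, seed=7)
        np.testing.assert_array_equal(ts.A[0], patterns.u1)
        np.testing.assert_array_equal(ts.A[-1], patterns.u2)

    def test_independent_of_training_noise(self, study):
        patterns, datasets = study
        ts = spl.make_test_set(patterns, 10, 1.0, seed=7)
        assert not np.array_equal(ts.A[:20], datasets[0].A)


class TestSnr:
    def test_closed_form_at_unit_scale(self):
        # standardized noise columns have sum of squares exactly t-1
        spec = spl.SimulationSpec(noise_scale=1.0, seed=2)
        p = spl.make_pattern_pair(spec)
        ds = spl.make_dataset(p, spec)
        tsnr, _ = spl.compute_snr(ds, p)
        assert np.isclose(tsnr, 10 * np.log10(10 / 19), atol=1e-9)

    def test_default_scale_sits_at_stated_operating_point(self, study):
        patterns, datasets = study
        tsnr, ssnr = spl.compute_snr(datasets[0], patterns)
        assert np.isclose(tsnr, 10 * np.log10(10 / 19), atol=1e-9)  # unit noise
        assert ssnr < tsnr  # spatial SNR is lower: only 25/300 entries carry signal

    def test_doubling_noise_costs_six_db(self):
        spec1 = spl.SimulationSpec(noise_scale=1.0, seed=3)
        spec2 = spl.SimulationSpec(noise_scale=2.0, seed=3)
        p = spl.make_pattern_pair(spec1)
        t1, _ = spl.compute_snr(spl.make_dataset(p, spec1), p)
        t2, _ = spl.compute_snr(spl.make_dataset(p, spec2), p)
        assert np.isclose(t1 - t2, 20 * np.log10(2), atol=1e-6)

    def test_snr_strictly_decreases_in_noise_scale(self):
        p = spl.make_pattern_pair(spl.SimulationSpec(seed=4))
        tsnrs = []
        for c in [0.5, 1.0, 2.0, 4.0]:
            spec = spl.SimulationSpec(noise_scale=c, seed=4)
            tsnrs.append(spl.compute_snr(spl.make_dataset(p, spec), p)[0])
        assert np.all(np.diff(tsnrs) < 0)

    def test_zero_noise_reports_infinite_snr(self):
        spec = spl.SimulationSpec(noise_scale=0.0, seed=0)
        p = spl.make_pattern_pair(spec)
        tsnr, ssnr = spl.compute_snr(spl.make_dataset(p, spec), p)
        assert np.isinf(tsnr) and np.isinf(ssnr)

    def test_all_zero_pattern_rejected(self):
        ds = spl.LabeledDataset(
            A=np.random.default_rng(0).standard_normal((4, 6)),
            y=np.array([1.0, 1.0, -1.0, -1.0]),
        )
        zeros = spl.PatternPair(u1=np.zeros(6), u2=np.zeros(6))
        with pytest.raises(ValueError):
            spl.compute_snr(ds, zeros)

    def test_noise_scale_for_tsnr_round_trips(self):
        c = noise_scale_for_tsnr(-12.0)
        spec = spl.SimulationSpec(noise_scale=c, seed=6)
        p = spl.make_pattern_pair(spec)
        assert np.isclose(spl.compute_snr(spl.make_dataset(p, spec), p)[0], -12.0, atol=1e-9)


class TestLabeledDatasetValidation:
    def test_row_label_mismatch(self):
        with pytest.raises(ValueError):
            spl.LabeledDataset(A=np.zeros((3, 2)), y=np.array([1.0, -1.0]))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            spl.LabeledDataset(A=np.zeros((2, 2)), y=np.array([1.0, 1.0]))

    def test_non_finite_rejected(self):
        A = np.zeros((2, 2))
        A[0, 0] = np.nan
        with pytest.raises(ValueError):
            spl.LabeledDataset(A=A, y=np.array([1.0, -1.0]))
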