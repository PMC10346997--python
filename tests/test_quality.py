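"""Signal-quality (SQT) rules: peaks, intervals, per-cycle statistics."""

import numpy as np
import pytest

from hankelppg import (
    QualityConfig,
    StatThresholds,
    assess_quality,
    calibrate_thresholds,
    check_interval_consistency,
    check_pulsatility,
    check_statistics,
    detect_peaks_valleys,
    window_statistics,
)
from hankelppg.quality import PeakSet, WindowStats, normalize_window

from tests_support import make_window

FS = 125.0


def peakset(n_peaks, n_valleys):
    p = np.arange(n_peaks) * 100
    v = np.arange(n_valleys) * 100 + 50
    return PeakSet(p, v, np.diff(p) / FS)


class TestDetectPeaksValleys:
    def test_sinusoid_counts(self):
        # 1.2 Hz over 6 s: 7 maxima and 7 minima of the sampled sinusoid
        t = np.arange(int(6 * FS)) / FS
        ps = detect_peaks_valleys(np.sin(2 * np.pi * 1.2 * t), FS)
        assert ps.n_peaks == 7
        assert ps.n_valleys == 7

    def test_constant_window_has_no_extrema(self):
        ps = detect_peaks_valleys(np.ones(int(6 * FS)), FS)
        assert ps.n_peaks == 0 and ps.n_valleys == 0

    def test_synthetic_beat_intervals(self):
        # 75 bpm -> 0.8 s inter-peak intervals, 10 peaks in 8 s
        ppg, _, _ = make_window(hr_bpm=75.0, noise_sd=0.0, drift_amp=0.0)
        ps = detect_peaks_valleys(normalize_window(ppg), FS)
        assert ps.n_peaks == 10
        assert np.allclose(ps.intervals_s, 0.8, atol=0.02)

    def test_window_shorter_than_two_cycles_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            detect_peaks_valleys(np.zeros(100), FS)

    def test_intervals_match_peak_indices(self):
        ppg, _, _ = make_window(seed=5)
        ps = detect_peaks_valleys(ppg, FS)
        assert len(ps.intervals_s) == max(0, ps.n_peaks - 1)
        assert np.all(ps.intervals_s > 0)
        assert np.all(np.diff(ps.peak_indices) > 0)


class TestChecks:
    @pytest.mark.parametrize("n_p,n_v,expected", [
        (7, 7, True), (7, 8, True), (7, 6, True),
        (7, 10, False), (7, 5, False), (2, 2, False),
    ])
    def test_pulsatility_band(self, n_p, n_v, expected):
        assert check_pulsatility(peakset(n_p, n_v)) is expected

    @pytest.mark.parametrize("intervals,expected", [
        ([0.80, 0.80, 0.80], True),
        # |0.87-0.80| = 0.07 <= 0.080 and |0.80-0.87| = 0.07 <= 0.087
        ([0.80, 0.87, 0.80], True),
        ([0.80, 0.95], False),  # 0.15 > 0.08
        ([0.80], False),        # insufficient evidence
        ([], False),
    ])
    def test_interval_rule(self, intervals, expected):
        assert check_interval_consistency(intervals, tol=0.1) is expected

    def test_statistics_bands(self):
        th = StatThresholds()
        good = WindowStats(np.array([1.5, 2.0]), np.array([0.0, 0.1]),
                           np.array([1.0, 0.9]))
        assert check_statistics(good, th)
        high_kurt = WindowStats(np.array([1.5, 5.0]), np.array([0.0, 0.1]),
                                np.array([1.0, 0.9]))
        assert not check_statistics(high_kurt, th)
        nonfinite = WindowStats(np.array([np.nan]), np.array([0.0]),
                                np.array([1.0]))
        assert not check_statistics(nonfinite, th)
        empty = WindowStats(np.array([]), np.array([]), np.array([]))
        assert not check_statistics(empty, th)


class TestWindowStatistics:
    def test_sinusoid_cycle_kurtosis(self):
        # analytic kurtosis of a sinusoid is 1.5
        t = np.arange(int(8 * FS)) / FS
        w = normalize_window(np.sin(2 * np.pi * 1.0 * t))
        ps = detect_peaks_valleys(w, FS)
        stats = window_statistics(w, ps)
        assert np.allclose(stats.kurtosis, 1.5, atol=0.05)
        assert stats.n_cycles == ps.n_peaks - 1

    def test_gaussian_cycle_kurtosis_near_three(self, rng):
        w = rng.standard_normal(4000)
        w = (w - w.mean()) / w.std()
        ps = PeakSet(np.array([0, 3999]), np.array([], dtype=int),
                     np.array([3999 / FS]))
        stats = window_statistics(w, ps)
        assert abs(stats.kurtosis[0] - 3.0) < 0.3

    def test_constant_cycle_flagged_nonfinite(self):
        w = np.zeros(1000)
        ps = PeakSet(np.array([10, 500]), np.array([], dtype=int),
                     np.array([490 / FS]))
        stats = window_statistics(w, ps)
        assert not np.isfinite(stats.kurtosis[0])
        assert stats.std[0] == 0.0
        assert not check_statistics(stats, StatThresholds())

    def test_single_peak_rejected(self):
        w = np.zeros(1000)
        ps = PeakSet(np.array([10]), np.array([], dtype=int), np.array([]))
        with pytest.raises(ValueError, match="two peaks"):
            window_statistics(w, ps)


class TestAssessQuality:
    def test_clean_window_qualifies(self):
        ppg, _, _ = make_window(hr_bpm=72.0, seed=1)
        report = assess_quality(ppg, FS)
        assert report.sqt == 1
        assert report.pulsatility_ok and report.intervals_ok \
            and report.stats_ok

    def test_heavy_noise_and_drift_disqualify(self):
        # same beat plus 0.3 Hz drift and white noise at 5x the AC amplitude
        ppg, _, truth = make_window(hr_bpm=72.0, seed=1, prefilter=False)
        t = np.arange(len(ppg)) / FS
        rng = np.random.default_rng(9)
        rms = np.sqrt(np.mean(truth.clean_ppg ** 2))
        bad = (truth.clean_ppg + 5 * rms * np.sin(2 * np.pi * 0.3 * t)
               + 5 * rms * rng.standard_normal(len(t)))
        report = assess_quality(bad, FS)
        assert report.sqt == 0

    def test_all_zero_window_fails_pulsatility(self):
        report = assess_quality(np.zeros(int(8 * FS)), FS)
        assert report.sqt == 0
        assert not report.pulsatility_ok

    def test_amplitude_and_offset_invariance(self):
        ppg, _, _ = make_window(seed=7)
        base = assess_quality(ppg, FS)
        scaled = assess_quality(3.7 * ppg + 250.0, FS)
        assert scaled.sqt == base.sqt
        assert scaled.pulsatility_ok == base.pulsatility_ok
        assert np.array_equal(scaled.peaks.peak_indices,
                              base.peaks.peak_indices)

    def test_deterministic(self):
        ppg, _, _ = make_window(seed=3)
        r1 = assess_quality(ppg, FS)
        r2 = assess_quality(ppg, FS)
        assert r1.sqt == r2.sqt
        assert np.array_equal(r1.peaks.peak_indices, r2.peaks.peak_indices)

    def test_sqt_iff_all_checks(self):
        for seed in range(10):
            for ratio in (0.0, 5.0):
                ppg, _, _ = make_window(seed=seed, artifact_ratio=ratio)
                r = assess_quality(ppg, FS)
                assert (r.sqt == 1) == (r.pulsatility_ok and r.intervals_ok
                                        and r.stats_ok)


class TestCalibration:
    def test_bands_cover_clean_windows(self):
        windows = [make_window(hr_bpm=60 + 4 * i, seed=i)[0]
                   for i in range(10)]
        th = calibrate_thresholds(windows, FS)
        assert th.kurtosis[0] < th.kurtosis[1]
        assert th.mean[0] < th.mean[1]
        assert th.std[0] < th.std[1]
        cfg = QualityConfig(thresholds=th)
        ok = sum(assess_quality(w, FS, cfg).sqt for w in windows)
        # [1, 99] percentile bands clip the extreme cycles, so a window or
        # three may legitimately fall outside its own calibration
        assert ok >= 7
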