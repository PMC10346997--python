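"""Signal-quality gating for PPG windows (the SQT sub-algorithm).

A window is labelled with a binary Signal Quality Token (SQT): 1 if it is
clean enough for heart-rate estimation, 0 otherwise.  Three checks run in
sequence and short-circuit on the first failure:

1. **Pulsatility** — the counts of local maxima (peaks) and minima
   (valleys) may differ by at most one, and at least ``min_beats`` peaks
   must be present.  A pulsatile waveform alternates extrema, so a larger
   imbalance indicates a non-pulsatile or broken signal.
2. **Interval consistency** — every consecutive pair of inter-peak
   intervals ``t_i`` must satisfy ``|t_{i+1} - t_i| <= tol * t_i``
   (default tol = 0.1): heart rate drifts slowly relative to an 8-s window.
3. **Per-cycle statistics** — kurtosis, mean and standard deviation of each
   inter-peak cycle of the detrended, z-normalized window must fall inside
   configured bands.  A clean pulse cycle is sub-Gaussian (a sinusoid has
   kurtosis 1.5), so heavy-tailed cycles betray spikes and artifacts.

All checks operate on a linearly detrended, z-normalized copy of the
window, which makes the label invariant under affine amplitude changes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import scipy.signal
import scipy.stats

from .config import QualityConfig, StatThresholds


@dataclass
class PeakSet:
    """Detected local extrema of one PPG window."""

    peak_indices: np.ndarray
    valley_indices: np.ndarray
    intervals_s: np.ndarray  # time between consecutive peaks

    @property
    def n_peaks(self) -> int:
        return len(self.peak_indices)

    @property
    def n_valleys(self) -> int:
        return len(self.valley_indices)


@dataclass
class WindowStats:
    """Per-cycle statistics of a normalized window (one triple per cycle)."""

    kurtosis: np.ndarray
    mean: np.ndarray
    std: np.ndarray

    @property
    def n_cycles(self) -> int:
        return len(self.kurtosis)


@dataclass
class QualityReport:
    """Outcome of the full quality check for one window."""

    sqt: int
    pulsatility_ok: bool
    intervals_ok: bool
    stats_ok: bool
    peaks: Optional[PeakSet] = None
    stats: Optional[WindowStats] = None
    reason: str = ""


def normalize_window(window: np.ndarray) -> np.ndarray:
    """Linearly detrend and z-normalize a window.

    A constant (zero-variance) window is returned as all zeros.
    """
    w = np.asarray(window, dtype=float)
    w = scipy.signal.detrend(w, type="linear")
    sd = w.std()
    if sd == 0:
        return np.zeros_like(w)
    return (w - w.mean()) / sd


def detect_peaks_valleys(window: Sequence[float], fs: float,
                         hr_band: Tuple[float, float] = (0.7, 3.5),
                         prominence_frac: float = 0.25) -> PeakSet:
    """Detect peaks and valleys of one PPG window.

    Peaks are local maxima separated by at least one period of the fastest
    admissible heart rate (``1 / hr_band[1]`` seconds) with prominence at
    least ``prominence_frac`` of the window standard deviation; valleys are
    found analogously on the negated signal.
    """
    w = np.asarray(window, dtype=float)
    lo, hi = hr_band
    if fs <= 0:
        raise ValueError(f"fs must be positive, got {fs}")
    min_len = int(np.ceil(2 * fs / lo))
    if len(w) < min_len:
        raise ValueError(
            f"window of {len(w)} samples is shorter than two cycles at the "
            f"slowest admissible HR ({min_len} samples at fs={fs})"
        )
    distance = max(1, int(round(fs / hi)))
    prominence = prominence_frac * w.std()
    if prominence == 0:
        # constant window: no extrema by definition
        empty = np.array([], dtype=int)
        return PeakSet(empty, empty, np.array([], dtype=float))
    peaks, _ = scipy.signal.find_peaks(w, distance=distance,
                                       prominence=prominence)
    valleys, _ = scipy.signal.find_peaks(-w, distance=distance,
                                         prominence=prominence)
    intervals = np.diff(peaks) / fs
    return PeakSet(peaks, valleys, intervals)


def check_pulsatility(peaks: PeakSet, min_beats: int = 3) -> bool:
    """Peak/valley count balance: ``|n_valleys - n_peaks| <= 1``.

    Also requires at least ``min_beats`` peaks so a near-flat window with a
    single bump does not qualify.
    """
    return (abs(peaks.n_valleys - peaks.n_peaks) <= 1
            and peaks.n_peaks >= min_beats)


def check_interval_consistency(intervals_s: Sequence[float],
                               tol: float = 0.1) -> bool:
    """Consecutive inter-peak intervals must agree to within ``tol``.

    True iff ``|t_{i+1} - t_i| <= tol * t_i`` for every consecutive pair.
    Fewer than two intervals is insufficient evidence of pulsation and
    returns False.
    """
    t = np.asarray(intervals_s, dtype=float)
    if len(t) < 2:
        return False
    return bool(np.all(np.abs(np.diff(t)) <= tol * t[:-1]))


def _cycle_slices(peaks: PeakSet, n: int, segmentation: str):
    idx = peaks.peak_indices if segmentation == "peak" else peaks.valley_indices
    return [(idx[i], idx[i + 1]) for i in range(len(idx) - 1)]


def window_statistics(window: Sequence[float], peaks: PeakSet,
                      excess: bool = False,
                      segmentation: str = "peak") -> WindowStats:
    """Kurtosis, mean and std of each inter-peak cycle.

    The window is expected to be normalized (zero mean, unit variance);
    :func:`assess_quality` guarantees this.  Kurtosis is the fourth
    standardized moment (Pearson; normal = 3) unless ``excess`` is set.
    A constant cycle has undefined kurtosis and is reported as NaN, which
    :func:`check_statistics` treats as a failure.
    """
    w = np.asarray(window, dtype=float)
    slices = _cycle_slices(peaks, len(w), segmentation)
    if not slices:
        raise ValueError("need at least two peaks (one full cycle)")
    kurt, mean, std = [], [], []
    for a, b in slices:
        seg = w[a:b]
        mean.append(seg.mean())
        std.append(seg.std())
        if seg.std() == 0:
            kurt.append(np.nan)
        else:
            kurt.append(scipy.stats.kurtosis(seg, fisher=excess, bias=True))
    return WindowStats(np.asarray(kurt), np.asarray(mean), np.asarray(std))


def check_statistics(stats: WindowStats,
                     thresholds: StatThresholds) -> bool:
    """True iff every cycle's (kurtosis, mean, std) lies in all three bands.

    Non-finite statistics and empty cycle sets fail.
    """
    if stats.n_cycles == 0:
        return False
    arrays = (stats.kurtosis, stats.mean, stats.std)
    bands = (thresholds.kurtosis, thresholds.mean, thresholds.std)
    for arr, (lo, hi) in zip(arrays, bands):
        if not np.all(np.isfinite(arr)):
            return False
        if np.any(arr < lo) or np.any(arr > hi):
            return False
    return True


def assess_quality(window: Sequence[float], fs: float,
                   config: Optional[QualityConfig] = None) -> QualityReport:
    """Run the full quality check on one window and assign the SQT.

    The checks run in sequence — pulsatility, interval consistency,
    per-cycle statistics — short-circuiting to ``sqt=0`` on the first
    failure.  ``sqt=1`` iff all three pass.
    """
    cfg = config if config is not None else QualityConfig()
    w = normalize_window(window)
    try:
        peaks = detect_peaks_valleys(w, fs, hr_band=cfg.hr_band,
                                     prominence_frac=cfg.prominence_frac)
    except ValueError as exc:
        return QualityReport(sqt=0, pulsatility_ok=False, intervals_ok=False,
                             stats_ok=False, reason=str(exc))
    if not check_pulsatility(peaks, min_beats=cfg.min_beats):
        return QualityReport(sqt=0, pulsatility_ok=False, intervals_ok=False,
                             stats_ok=False, peaks=peaks,
                             reason="pulsatility check failed")
    if not check_interval_consistency(peaks.intervals_s, tol=cfg.interval_tol):
        return QualityReport(sqt=0, pulsatility_ok=True, intervals_ok=False,
                             stats_ok=False, peaks=peaks,
                             reason="inter-peak intervals inconsistent")
    try:
        stats = window_statistics(w, peaks, excess=cfg.excess_kurtosis,
                                  segmentation=cfg.segmentation)
    except ValueError as exc:
        return QualityReport(sqt=0, pulsatility_ok=True, intervals_ok=True,
                             stats_ok=False, peaks=peaks, reason=str(exc))
    if not check_statistics(stats, cfg.thresholds):
        return QualityReport(sqt=0, pulsatility_ok=True, intervals_ok=True,
                             stats_ok=False, peaks=peaks, stats=stats,
                             reason="cycle statistics out of bounds")
    return QualityReport(sqt=1, pulsatility_ok=True, intervals_ok=True,
                         stats_ok=True, peaks=peaks, stats=stats)


def calibrate_thresholds(windows: Sequence[Sequence[float]], fs: float,
                         config: Optional[QualityConfig] = None,
                         percentiles: Tuple[float, float] = (1.0, 99.0),
                         ) -> StatThresholds:
    """Fit statistic accept-bands from a set of known-clean windows.

    Pools the per-cycle statistics over all windows (using the current
    peak-detection settings) and returns the [lo, hi] percentile band for
    each statistic.
    """
    cfg = config if config is not None else QualityConfig()
    pooled = {"kurtosis": [], "mean": [], "std": []}
    for window in windows:
        w = normalize_window(window)
        peaks = detect_peaks_valleys(w, fs, hr_band=cfg.hr_band,
                                     prominence_frac=cfg.prominence_frac)
        if peaks.n_peaks < 2:
            continue
        stats = window_statistics(w, peaks, excess=cfg.excess_kurtosis,
                                  segmentation=cfg.segmentation)
        pooled["kurtosis"].append(stats.kurtosis)
        pooled["mean"].append(stats.mean)
        pooled["std"].append(stats.std)
    if not pooled["kurtosis"]:
        raise ValueError("no usable cycles found in the calibration windows")
    bands = {}
    for key, chunks in pooled.items():
        values = np.concatenate(chunks)
        values = values[np.isfinite(values)]
        bands[key] = (float(np.percentile(values, percentiles[0])),
                      float(np.percentile(values, percentiles[1])))
    return StatThresholds(kurtosis=bands["kurtosis"], mean=bands["mean"],
                          std=bands["std"])
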