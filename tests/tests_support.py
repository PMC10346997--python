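"""Helpers shared across test modules (not fixtures)."""

from __future__ import annotations

import numpy as np

from hankelppg import SynthParams, generate
from hankelppg.pipeline import bandpass_filter

FS = 125.0


def make_window(hr_bpm: float = 72.0, duration_s: float = 8.0,
                artifact_ratio: float = 0.0, motion_freq_hz: float = 2.0,
                noise_sd: float = 0.05, drift_amp: float = 0.3,
                seed: int = 0, prefilter: bool = True):
    """One synthetic PPG window plus its record and truth."""
    params = SynthParams(duration_s=duration_s, hr_profile=hr_bpm,
                         artifact_ratio=artifact_ratio,
                         motion_freq_hz=motion_freq_hz,
                         noise_sd=noise_sd, drift_amp=drift_amp, seed=seed)
    rec, truth = generate(params)
    ppg = bandpass_filter(rec.ppg, FS) if prefilter else rec.ppg
    return ppg, rec, truth


def corrupted_window_with_truth(seed: int = 0, hr_bpm: float = 75.0,
                                motion_freq_hz: float = 2.0,
                                artifact_ratio: float = 2.0,
                                duration_s: float = 8.0):
    """Pre-filtered corrupted PPG window, its accel matrix and clean truth."""
    params = SynthParams(duration_s=duration_s, hr_profile=hr_bpm,
                         motion_freq_hz=motion_freq_hz,
                         artifact_ratio=artifact_ratio, seed=seed)
    rec, truth = generate(params)
    ppg = bandpass_filter(rec.ppg, FS)
    accel = np.vstack([bandpass_filter(a, FS)
                       for a in (rec.accel_x, rec.accel_y, rec.accel_z)])
    clean = bandpass_filter(truth.clean_ppg, FS)
    return ppg, accel, clean
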