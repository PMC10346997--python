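"""Seeded synthetic PPG + accelerometer records with known ground truth.

The generator emulates the signal structure the estimation method assumes:

* a quasi-periodic pulsatile component — a truncated harmonic series whose
  instantaneous frequency follows a prescribed heart-rate profile
  (40-180 bpm);
* low-frequency baseline drift (low-pass-filtered seeded noise), mimicking
  the large DC wander of wrist PPG during movement;
* an additive motion artifact — a cadence fundamental (0.5-3 Hz) plus
  harmonics with random phases — that is *shared* with the acceleration
  channels through per-axis coupling gains, exactly the situation the
  correlation-based component rejection exploits;
* white sensor noise.

Every record is fully determined by its :class:`SynthParams` (including the
seed), and the clean pulsatile series plus the per-window true HR are
returned alongside the record for oracle-style testing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import scipy.signal

from .io import SensorRecord

#: heart-rate profile: constant bpm or piecewise-linear (time_s, bpm) knots
HRProfile = Union[float, Sequence[Tuple[float, float]]]


@dataclass
class SynthParams:
    """Generative parameters for one synthetic record.

    Amplitude-like parameters (``artifact_ratio``, ``drift_amp``,
    ``noise_sd``) are expressed relative to the RMS of the pulsatile
    component, so ``artifact_ratio=2`` means the motion artifact carries
    twice the pulsatile RMS.
    """

    duration_s: float = 60.0
    fs: float = 125.0
    hr_profile: HRProfile = 72.0
    #: relative amplitudes of the beat-template harmonics
    pulse_shape: Tuple[float, ...] = (1.0, 0.4, 0.15)
    #: walking/hand cadence in Hz
    motion_freq_hz: float = 2.0
    motion_harmonics: int = 3
    #: artifact RMS / pulsatile RMS
    artifact_ratio: float = 0.0
    #: drift RMS / pulsatile RMS
    drift_amp: float = 0.3
    drift_cutoff_hz: float = 0.15
    #: white-noise SD / pulsatile RMS
    noise_sd: float = 0.05
    #: per-axis artifact gain into the accelerometer
    accel_coupling: Tuple[float, float, float] = (1.0, 0.6, 0.3)
    #: accelerometer's own noise SD relative to the artifact RMS
    accel_noise_sd: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        if self.duration_s <= 0 or self.fs <= 0:
            raise ValueError("duration_s and fs must be positive")
        for name in ("artifact_ratio", "drift_amp", "noise_sd",
                     "accel_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        hr = self._hr_knots()
        if np.any(hr[:, 1] < 40) or np.any(hr[:, 1] > 180):
            raise ValueError("hr_profile must stay within [40, 180] bpm")
        f_beat = len(self.pulse_shape) * hr[:, 1].max() / 60.0
        f_motion = self.motion_harmonics * self.motion_freq_hz
        f_max = max(f_beat, f_motion)
        if self.fs <= 2 * f_max:
            raise ValueError(
                f"fs={self.fs} must exceed twice the highest generated "
                f"frequency ({f_max:.2f} Hz)"
            )

    def _hr_knots(self) -> np.ndarray:
        if np.isscalar(self.hr_profile):
            return np.array([[0.0, float(self.hr_profile)],
                             [self.duration_s, float(self.hr_profile)]])
        knots = np.asarray(self.hr_profile, dtype=float)
        if knots.ndim != 2 or knots.shape[1] != 2:
            raise ValueError("hr_profile knots must be (time_s, bpm) pairs")
        return knots


@dataclass
class SynthTruth:
    """Ground truth accompanying a generated record."""

    clean_ppg: np.ndarray  # pulsatile component only
    artifact: np.ndarray
    hr_bpm: np.ndarray  # instantaneous true HR per sample
    fs: float

    def window_hr(self, window_s: float, hop_s: float) -> np.ndarray:
        """Mean true HR over each analysis window (matching the pipeline)."""
        win = int(round(window_s * self.fs))
        hop = int(round(hop_s * self.fs))
        n = len(self.hr_bpm)
        starts = range(0, n - win + 1, hop)
        return np.array([self.hr_bpm[s:s + win].mean() for s in starts])


def _rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(x ** 2)))


def generate(params: SynthParams) -> Tuple[SensorRecord, SynthTruth]:
    """Generate one synthetic record; identical params give identical data."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration_s * params.fs))
    t = np.arange(n) / params.fs

    knots = params._hr_knots()
    hr_t = np.interp(t, knots[:, 0], knots[:, 1])
    # beat phase in cycles; random initial phase decorrelates batches
    phase = np.cumsum(hr_t / 60.0) / params.fs + rng.uniform(0, 1)
    clean = np.zeros(n)
    for k, amp in enumerate(params.pulse_shape, start=1):
        clean += amp * np.sin(2 * np.pi * k * phase)
    pulsatile_rms = _rms(clean) if _rms(clean) > 0 else 1.0

    # baseline drift: low-pass-filtered white noise
    drift = np.zeros(n)
    if params.drift_amp > 0:
        raw = rng.standard_normal(n)
        wn = params.drift_cutoff_hz / (params.fs / 2)
        b, a = scipy.signal.butter(2, wn, btype="low")
        drift = scipy.signal.filtfilt(b, a, raw)
        d_rms = _rms(drift)
        if d_rms > 0:
            drift *= params.drift_amp * pulsatile_rms / d_rms

    # motion artifact: cadence fundamental + harmonics, random phases
    artifact = np.zeros(n)
    if params.artifact_ratio > 0:
        psi = rng.uniform(0, 2 * np.pi, size=params.motion_harmonics)
        for h in range(1, params.motion_harmonics + 1):
            artifact += (1.0 / h) * np.sin(
                2 * np.pi * h * params.motion_freq_hz * t + psi[h - 1])
        a_rms = _rms(artifact)
        if a_rms > 0:
            artifact *= params.artifact_ratio * pulsatile_rms / a_rms

    noise = params.noise_sd * pulsatile_rms * rng.standard_normal(n)
    ppg = clean + drift + artifact + noise

    artifact_rms = _rms(artifact)
    accel = []
    for gain in params.accel_coupling:
        own_noise = (params.accel_noise_sd * artifact_rms
                     * rng.standard_normal(n))
        accel.append(gain * artifact + own_noise)

    rec = SensorRecord(
        ppg=ppg, accel_x=accel[0], accel_y=accel[1], accel_z=accel[2],
        fs=params.fs, record_id=f"synth-{params.seed}",
    )
    truth = SynthTruth(clean_ppg=clean, artifact=artifact, hr_bpm=hr_t,
                       fs=params.fs)
    return rec, truth


def generate_batch(n: int, seed: int,
                   param_ranges: Optional[dict] = None,
                   base: Optional[SynthParams] = None):
    """Generate ``n`` records with per-record seeds derived from ``seed``.

    ``param_ranges`` maps :class:`SynthParams` field names to ``(lo, hi)``
    ranges sampled uniformly per record (scalars are passed through).
    Yields ``(params, record, truth)`` triples.
    """
    rng = np.random.default_rng(seed)
    base = base if base is not None else SynthParams()
    param_ranges = param_ranges or {}
    for _ in range(n):
        overrides = {}
        for name, spec in param_ranges.items():
            if np.isscalar(spec):
                overrides[name] = spec
            else:
                lo, hi = spec
                overrides[name] = float(rng.uniform(lo, hi))
        overrides["seed"] = int(rng.integers(0, 2 ** 31))
        params = replace(base, **overrides)
        rec, truth = generate(params)
        yield params, rec, truth
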