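"""Spectral heart-rate estimation with temporal tracking.

The cleaned window is zero-meaned, zero-padded and Fourier transformed;
the heart rate is the frequency of the largest magnitude peak inside the
physiological band (0.7-3.5 Hz by default, i.e. 42-210 bpm).  Consecutive
estimates are constrained to be close to each other: the search is first
restricted to a +-``max_jump_bpm`` band around the previous estimate and
only abandoned (with ``tracked=False``) when no credible peak lives there.

A notch-filter motion-artifact-removal variant for hand movement is also
provided: the dominant cadence is read off the summed accelerometer
spectra and suppressed with a zero-phase IIR notch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import scipy.signal

from .config import SpectralConfig, TrackConfig


@dataclass
class Spectrum:
    """One-sided magnitude spectrum of a window."""

    freqs: np.ndarray
    mags: np.ndarray
    fs: float
    nfft: int


@dataclass
class HREstimate:
    """Heart-rate estimate for one window."""

    hr_bpm: float
    peak_freq_hz: float
    tracked: bool
    sqt: int = 1
    carried: bool = False  # previous HR carried forward (no fresh estimate)


def min_nfft(fs: float, resolution_bpm: float = 0.5) -> int:
    """Smallest power-of-two FFT length giving the target bpm grid."""
    # fs / nfft <= resolution_bpm / 60 Hz
    n = 60.0 * fs / resolution_bpm
    return int(2 ** np.ceil(np.log2(n)))


def dft_spectrum(window: Sequence[float], fs: float,
                 nfft: Optional[int] = None,
                 taper: Optional[str] = "hann") -> Spectrum:
    """Magnitude spectrum of a zero-meaned, zero-padded window.

    A Hann taper (default) suppresses spectral-leakage sidelobes from
    about -13 dB (rectangular) to -31 dB, so a strong tone's sidelobes
    cannot masquerade as credible peaks elsewhere in the HR band; pass
    ``taper=None`` for the plain transform.
    """
    w = np.asarray(window, dtype=float)
    if w.size == 0:
        raise ValueError("window must be non-empty")
    if nfft is None:
        nfft = min_nfft(fs)
    if nfft < len(w):
        raise ValueError(f"nfft={nfft} shorter than window ({len(w)})")
    w = w - w.mean()
    if taper == "hann":
        w = w * np.hanning(len(w))
    elif taper is not None:
        raise ValueError(f"unknown taper {taper!r}")
    spec = np.fft.rfft(w, n=nfft)
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    return Spectrum(freqs=freqs, mags=np.abs(spec), fs=fs, nfft=nfft)


def _parabolic_refine(spec: Spectrum, k: int) -> float:
    """Refine the peak bin k by fitting a parabola through its neighbours."""
    m = spec.mags
    if not 0 < k < len(m) - 1:
        return spec.freqs[k]
    y0, y1, y2 = m[k - 1], m[k], m[k + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return spec.freqs[k]
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    df = spec.freqs[1] - spec.freqs[0]
    return spec.freqs[k] + delta * df


def _band_argmax(spec: Spectrum, lo_hz: float, hi_hz: float,
                 interp: bool) -> Optional[Tuple[float, float, bool]]:
    """(freq, magnitude, is_local_peak) of the band argmax in [lo, hi].

    ``is_local_peak`` is False when the argmax sits on a band edge with
    the magnitude still rising outward — i.e. it is the skirt of a peak
    outside the band, not a peak of its own.
    """
    mask = (spec.freqs >= lo_hz) & (spec.freqs <= hi_hz)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return None
    k = idx[np.argmax(spec.mags[idx])]
    # ties break toward the lower frequency via argmax's first-hit rule
    m = spec.mags
    is_peak = True
    if k == idx[0] and k > 0 and m[k - 1] > m[k]:
        is_peak = False
    if k == idx[-1] and k < len(m) - 1 and m[k + 1] > m[k]:
        is_peak = False
    freq = _parabolic_refine(spec, k) if interp else spec.freqs[k]
    return float(freq), float(m[k]), is_peak


def pick_hr(spec: Spectrum, hr_band: Tuple[float, float] = (0.7, 3.5),
            prev_hr: Optional[float] = None,
            track: Optional[TrackConfig] = None,
            parabolic_interp: bool = True, sqt: int = 1) -> HREstimate:
    """Select the heart-rate peak from a spectrum, with tracking.

    With no previous estimate the global band argmax is taken.  Otherwise
    the search is restricted to ``prev_hr +- max_jump_bpm``; if the best
    candidate there is weaker than ``rel_floor`` times the global band
    maximum, or is merely the band-edge skirt of a peak outside the
    tracking band rather than a local peak of its own, tracking is
    abandoned for this window and the global argmax is used.  If the
    tracking band does not intersect the HR band at all, the previous
    estimate is carried forward.
    """
    cfg = track if track is not None else TrackConfig()
    lo, hi = hr_band
    global_pick = _band_argmax(spec, lo, hi, parabolic_interp)
    if global_pick is None:
        raise ValueError("HR band contains no spectrum bins")
    if prev_hr is None:
        freq = global_pick[0]
        return HREstimate(hr_bpm=60.0 * freq, peak_freq_hz=freq,
                          tracked=False, sqt=sqt)
    sub_lo = max(lo, (prev_hr - cfg.max_jump_bpm) / 60.0)
    sub_hi = min(hi, (prev_hr + cfg.max_jump_bpm) / 60.0)
    if sub_lo > sub_hi:
        # tracking band fell outside the HR band: carry the previous HR
        return HREstimate(hr_bpm=prev_hr, peak_freq_hz=prev_hr / 60.0,
                          tracked=True, sqt=sqt, carried=True)
    sub_pick = _band_argmax(spec, sub_lo, sub_hi, parabolic_interp)
    global_mag = global_pick[1]
    if (sub_pick is not None and sub_pick[2]
            and sub_pick[1] >= cfg.rel_floor * global_mag):
        freq = sub_pick[0]
        # clamp interpolation drift back inside the tracking band
        freq = float(np.clip(freq, sub_lo, sub_hi))
        return HREstimate(hr_bpm=60.0 * freq, peak_freq_hz=freq,
                          tracked=True, sqt=sqt)
    freq = global_pick[0]
    return HREstimate(hr_bpm=60.0 * freq, peak_freq_hz=freq,
                      tracked=False, sqt=sqt)


def estimate_hr(window: Sequence[float], fs: float,
                config: Optional[SpectralConfig] = None,
                prev_hr: Optional[float] = None, sqt: int = 1) -> HREstimate:
    """Convenience wrapper: spectrum + peak picking in one call."""
    cfg = config if config is not None else SpectralConfig()
    spec = dft_spectrum(window, fs,
                        nfft=min_nfft(fs, cfg.nfft_resolution_bpm))
    return pick_hr(spec, hr_band=cfg.hr_band, prev_hr=prev_hr,
                   track=cfg.track, parabolic_interp=cfg.parabolic_interp,
                   sqt=sqt)


def detect_motion_frequency(accel: Sequence[Sequence[float]], fs: float,
                            band: Tuple[float, float] = (0.5, 5.0),
                            min_peak_ratio: float = 3.0,
                            ) -> Optional[float]:
    """Dominant cadence from the summed accelerometer magnitude spectra.

    Returns None when the summed spectrum is flat (peak below
    ``min_peak_ratio`` times the in-band median), i.e. no coherent motion.
    """
    accel = np.atleast_2d(np.asarray(accel, dtype=float))
    total = None
    for axis in accel:
        spec = dft_spectrum(axis, fs)
        total = spec.mags if total is None else total + spec.mags
    freqs = np.fft.rfftfreq(spec.nfft, d=1.0 / fs)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    in_band = total[mask]
    if in_band.size == 0 or in_band.max() == 0:
        return None
    med = np.median(in_band)
    if med > 0 and in_band.max() < min_peak_ratio * med:
        return None
    return float(freqs[mask][np.argmax(in_band)])


def notch_mar(ppg: Sequence[float], accel: Sequence[Sequence[float]],
              fs: float, q: float = 5.0,
              harmonics: int = 1) -> np.ndarray:
    """Notch-filter motion-artifact removal (hand-movement variant).

    Estimates the dominant motion frequency from the accelerometer and
    applies a zero-phase second-order notch at that frequency (and at its
    harmonics up to ``harmonics``).  Returns the PPG unchanged when the
    accelerometer shows no coherent motion.
    """
    x = np.asarray(ppg, dtype=float)
    if len(x) < 2 * fs:
        raise ValueError("need at least 2 s of samples for notch MAR")
    if q <= 0:
        raise ValueError(f"quality factor must be positive, got {q}")
    f0 = detect_motion_frequency(accel, fs)
    if f0 is None:
        return x.copy()
    out = x
    nyq = fs / 2.0
    for h in range(1, harmonics + 1):
        fh = h * f0
        if fh >= 0.95 * nyq:
            break
        b, a = scipy.signal.iirnotch(fh, Q=q, fs=fs)
        out = scipy.signal.filtfilt(b, a, out)
    return out
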