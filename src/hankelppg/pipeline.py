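"""End-to-end per-record processing.

For each overlapping analysis window (default 8 s, hop 2 s):

1. a zero-phase 0.4-10 Hz band-pass pre-filter is applied to all channels
   (once per record) to remove DC drift and out-of-band noise;
2. the quality check assigns the window's SQT;
3. if SQT = 1, motion artifacts are removed (Hankel/SVD by default, or the
   notch variant, or nothing) and the heart rate is estimated from the
   spectrum under the tracking rule;
4. if SQT = 0, the previous heart rate is carried forward and flagged.

The first window's tracking reference is the configured initial heart
rate (78 bpm).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
import scipy.signal

from .config import PipelineConfig
from .hankel_mar import remove_motion_artifacts
from .io import SensorRecord
from .quality import assess_quality
from .spectral import estimate_hr, notch_mar


@dataclass
class WindowEstimate:
    """One window of an HR trace."""

    window_start_s: float
    window_end_s: float
    hr_bpm: float
    sqt: int
    tracked: bool = True
    carried: bool = False


@dataclass
class HRTrace:
    """Ordered per-window HR estimates for one record."""

    estimates: List[WindowEstimate] = field(default_factory=list)
    record_id: str = ""

    def __len__(self) -> int:
        return len(self.estimates)

    @property
    def hr_bpm(self) -> np.ndarray:
        return np.array([e.hr_bpm for e in self.estimates])

    @property
    def sqt(self) -> np.ndarray:
        return np.array([e.sqt for e in self.estimates], dtype=int)


def bandpass_filter(x: np.ndarray, fs: float, band=(0.4, 10.0),
                    order: int = 3) -> np.ndarray:
    """Zero-phase Butterworth band-pass."""
    nyq = fs / 2.0
    lo, hi = band[0] / nyq, min(band[1] / nyq, 0.99)
    b, a = scipy.signal.butter(order, (lo, hi), btype="band")
    return scipy.signal.filtfilt(b, a, x)


def process_record(rec: SensorRecord,
                   cfg: Optional[PipelineConfig] = None) -> HRTrace:
    """Run the full two-stage HR-estimation pipeline on one record."""
    cfg = cfg if cfg is not None else PipelineConfig()
    win = int(round(cfg.window_s * rec.fs))
    hop = int(round(cfg.hop_s * rec.fs))
    n = len(rec)
    if n < win:
        raise ValueError(
            f"record of {n / rec.fs:.2f} s is shorter than one analysis "
            f"window ({cfg.window_s} s)"
        )

    ppg = bandpass_filter(rec.ppg, rec.fs, cfg.prefilter_band)
    accel = np.vstack([
        bandpass_filter(ax, rec.fs, cfg.prefilter_band)
        for ax in (rec.accel_x, rec.accel_y, rec.accel_z)
    ])

    trace = HRTrace(record_id=rec.record_id)
    prev_hr = cfg.spectral.track.init_hr
    for start in range(0, n - win + 1, hop):
        stop = start + win
        w_ppg = ppg[start:stop]
        w_accel = accel[:, start:stop]
        report = assess_quality(w_ppg, rec.fs, cfg.quality)
        if report.sqt == 1:
            if cfg.mar_method == "hankel":
                cleaned, _ = remove_motion_artifacts(
                    w_ppg, w_accel, cfg.hankel_mar)
            elif cfg.mar_method == "notch":
                cleaned = notch_mar(w_ppg, w_accel, rec.fs,
                                    q=cfg.spectral.notch_q,
                                    harmonics=cfg.spectral.notch_harmonics)
            else:
                cleaned = w_ppg
            est = estimate_hr(cleaned, rec.fs, cfg.spectral,
                              prev_hr=prev_hr, sqt=1)
            hr, tracked, carried = est.hr_bpm, est.tracked, est.carried
            prev_hr = hr
        else:
            hr, tracked, carried = prev_hr, True, True
        trace.estimates.append(WindowEstimate(
            window_start_s=start / rec.fs,
            window_end_s=stop / rec.fs,
            hr_bpm=hr, sqt=report.sqt, tracked=tracked, carried=carried,
        ))
    return trace
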