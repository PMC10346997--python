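"""Configuration dataclasses for the HR-estimation pipeline.

Every stage of the pipeline (quality gating, Hankel/SVD motion-artifact
removal, spectral HR estimation) is driven by a small dataclass; the full
:class:`PipelineConfig` nests them and can be round-tripped through YAML so
that runs are reproducible from a single file.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Tuple

import yaml


@dataclass
class StatThresholds:
    """Accept bands for the per-cycle statistics of a normalized window.

    The bands apply to each inter-peak cycle of a linearly detrended,
    z-normalized PPG window.  Kurtosis uses the Pearson convention
    (a Gaussian scores 3, a pure sinusoid 1.5) unless ``excess_kurtosis``
    is set on :class:`QualityConfig`.
    """

    kurtosis: Tuple[float, float] = (1.0, 4.0)
    mean: Tuple[float, float] = (-0.5, 0.5)
    std: Tuple[float, float] = (0.3, 1.7)


@dataclass
class QualityConfig:
    """Parameters of the signal-quality (SQT) sub-algorithm."""

    window_s: float = 8.0
    #: physiological HR search band in Hz (42-210 bpm by default)
    hr_band: Tuple[float, float] = (0.7, 3.5)
    #: max fractional change between consecutive inter-peak intervals
    interval_tol: float = 0.1
    #: minimum number of detected peaks for the pulsatility check
    min_beats: int = 3
    #: peak prominence as a fraction of the window standard deviation
    prominence_frac: float = 0.25
    thresholds: StatThresholds = field(default_factory=StatThresholds)
    #: kurtosis convention: False -> Pearson (normal=3), True -> excess
    excess_kurtosis: bool = False
    #: cycle segmentation: "peak" (peak-to-peak) or "valley"
    segmentation: str = "peak"


@dataclass
class HankelMarConfig:
    """Parameters of the Hankel/SVD motion-artifact removal stage."""

    #: absolute Pearson correlation above which a component is motion-related
    threshold: float = 0.5
    #: cap on removed components; None means r - 1 (at least one is kept)
    max_remove: Optional[int] = None
    #: "accel_components" (default) correlates against the dominant
    #: component series of each axis' own embedding, which separates the
    #: motion harmonics and their spectral quadratures into individual
    #: reference tones; "raw_accel" correlates against the raw axes
    correlation_mode: str = "accel_components"
    #: optional energy floor: additionally drop components whose singular
    #: value falls below this fraction of the largest (None = disabled)
    energy_floor: Optional[float] = None
    #: "projection" (default) subtracts each flagged component's
    #: least-squares projection onto the reference span; "full" subtracts
    #: the whole component series
    removal: str = "projection"


@dataclass
class TrackConfig:
    """Temporal-tracking rule for consecutive HR estimates."""

    max_jump_bpm: float = 10.0
    init_hr: float = 78.0
    #: tracked sub-band peak must reach this fraction of the global band
    #: maximum (and be a local peak, not a band-edge skirt), otherwise
    #: tracking is abandoned for the window
    rel_floor: float = 0.2


@dataclass
class SpectralConfig:
    """Spectral HR estimation parameters."""

    hr_band: Tuple[float, float] = (0.7, 3.5)
    #: frequency-grid resolution target in bpm (sets the FFT zero padding)
    nfft_resolution_bpm: float = 0.5
    #: refine the peak location by parabolic interpolation on log magnitude
    parabolic_interp: bool = True
    track: TrackConfig = field(default_factory=TrackConfig)
    #: notch-filter MAR variant
    notch_q: float = 5.0
    notch_harmonics: int = 1


@dataclass
class PipelineConfig:
    """End-to-end per-record processing parameters."""

    window_s: float = 8.0
    hop_s: float = 2.0
    mar_method: str = "hankel"  # "hankel" | "notch" | "none"
    #: zero-phase band-pass applied to all channels before windowing, Hz
    prefilter_band: Tuple[float, float] = (0.4, 10.0)
    quality: QualityConfig = field(default_factory=QualityConfig)
    hankel_mar: HankelMarConfig = field(default_factory=HankelMarConfig)
    spectral: SpectralConfig = field(default_factory=SpectralConfig)

    def __post_init__(self) -> None:
        if not (0 < self.hop_s <= self.window_s):
            raise ValueError(
                f"hop_s must satisfy 0 < hop_s <= window_s, got "
                f"hop_s={self.hop_s}, window_s={self.window_s}"
            )
        if self.mar_method not in ("hankel", "notch", "none"):
            raise ValueError(f"unknown mar_method {self.mar_method!r}")
        # keep the quality stage's window in sync unless explicitly overridden
        self.quality.window_s = self.window_s


def _asdict(cfg) -> dict:
    return dataclasses.asdict(cfg)


_NESTED = {
    "thresholds": StatThresholds,
    "quality": QualityConfig,
    "hankel_mar": HankelMarConfig,
    "spectral": SpectralConfig,
    "track": TrackConfig,
}


def _from_dict(cls, data: dict):
    kwargs = {}
    valid = {f.name for f in dataclasses.fields(cls)}
    for key, value in data.items():
        if key not in valid:
            raise ValueError(f"unknown config key {key!r} for {cls.__name__}")
        if key in _NESTED and isinstance(value, dict):
            value = _from_dict(_NESTED[key], value)
        elif isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


def load_config(path) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from a YAML file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return _from_dict(PipelineConfig, data)


def save_config(cfg: PipelineConfig, path) -> None:
    """Serialize a :class:`PipelineConfig` to YAML."""
    with open(path, "w") as fh:
        yaml.safe_dump(_asdict(cfg), fh, sort_keys=False)
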