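"""Reading and writing sensor records and HR traces.

Three on-disk formats are supported:

* a plain CSV record format with columns ``time`` (optional), ``ppg``,
  ``ax``, ``ay``, ``az``;
* MATLAB v5 ``.mat`` records in the IEEE Signal Processing Cup 2015 layout
  (a 6-row signal matrix — ECG, two PPG channels, three acceleration axes —
  sampled at 125 Hz, with an optional companion ground-truth file holding
  one BPM value per analysis window);
* a CSV heart-rate trace with one row per analysis window.

All loaders validate finiteness and channel lengths up front so that the
numerical stages never see NaNs or ragged channels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import scipy.io


class FormatError(ValueError):
    """Raised when an input file does not match the expected layout."""


SPC2015_FS = 125.0
#: default SPC-2015 row layout: ECG, PPG1, PPG2, accel x, y, z
SPC2015_ROWS = {"ecg": 0, "ppg1": 1, "ppg2": 2, "ax": 3, "ay": 4, "az": 5}


@dataclass
class SensorRecord:
    """Synchronized single-channel PPG and 3-axis accelerometer streams.

    Parameters
    ----------
    ppg, accel_x, accel_y, accel_z
        Equal-length sample arrays in arbitrary (ADC) units.
    fs
        Sampling rate in Hz, > 0.
    ref_hr
        Optional reference heart-rate trace (bpm, one value per analysis
        window of the source dataset).
    record_id
        Free-text label.
    """

    ppg: np.ndarray
    accel_x: np.ndarray
    accel_y: np.ndarray
    accel_z: np.ndarray
    fs: float
    ref_hr: Optional[np.ndarray] = None
    record_id: str = ""

    def __post_init__(self) -> None:
        self.ppg = np.asarray(self.ppg, dtype=float)
        self.accel_x = np.asarray(self.accel_x, dtype=float)
        self.accel_y = np.asarray(self.accel_y, dtype=float)
        self.accel_z = np.asarray(self.accel_z, dtype=float)
        n = len(self.ppg)
        if n < 1:
            raise ValueError("record must contain at least one sample")
        for name in ("accel_x", "accel_y", "accel_z"):
            if len(getattr(self, name)) != n:
                raise ValueError(
                    f"channel length mismatch: ppg has {n} samples, "
                    f"{name} has {len(getattr(self, name))}"
                )
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        for name in ("ppg", "accel_x", "accel_y", "accel_z"):
            arr = getattr(self, name)
            bad = np.flatnonzero(~np.isfinite(arr))
            if bad.size:
                raise ValueError(
                    f"non-finite samples in {name} at indices "
                    f"{bad[:10].tolist()}{'...' if bad.size > 10 else ''}"
                )
        if self.ref_hr is not None:
            self.ref_hr = np.asarray(self.ref_hr, dtype=float).ravel()

    def __len__(self) -> int:
        return len(self.ppg)

    @property
    def duration_s(self) -> float:
        return len(self.ppg) / self.fs

    @property
    def accel(self) -> np.ndarray:
        """The three acceleration axes stacked as a (3, n) array."""
        return np.vstack([self.accel_x, self.accel_y, self.accel_z])


_CSV_COLUMNS = ("ppg", "ax", "ay", "az")
# accepted aliases for the acceleration columns
_ALIASES = {"accel_x": "ax", "accel_y": "ay", "accel_z": "az"}


def read_csv_record(path, fs: float | str = "from time column",
                    record_id: Optional[str] = None) -> SensorRecord:
    """Read a sensor record from CSV.

    ``fs`` may be a sampling rate in Hz or the string
    ``"from time column"``, in which case the rate is inferred as
    ``1 / median(diff(time))`` from a monotonic ``time`` column (seconds).
    """
    df = pd.read_csv(path)
    df = df.rename(columns=_ALIASES)
    for col in _CSV_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} in {path}")
    if isinstance(fs, str):
        if "time" not in df.columns:
            raise FormatError(
                f"no 'time' column in {path}; pass fs explicitly"
            )
        t = df["time"].to_numpy(dtype=float)
        dt = np.diff(t)
        if len(dt) == 0 or np.any(dt <= 0):
            raise FormatError(f"time column in {path} is not strictly increasing")
        fs_val = 1.0 / float(np.median(dt))
    else:
        fs_val = float(fs)
        if "time" in df.columns:
            t = df["time"].to_numpy(dtype=float)
            if len(t) > 1 and np.any(np.diff(t) <= 0):
                raise FormatError(f"time column in {path} is not strictly increasing")
    return SensorRecord(
        ppg=df["ppg"].to_numpy(dtype=float),
        accel_x=df["ax"].to_numpy(dtype=float),
        accel_y=df["ay"].to_numpy(dtype=float),
        accel_z=df["az"].to_numpy(dtype=float),
        fs=fs_val,
        record_id=record_id if record_id is not None else str(path),
    )


def write_csv_record(rec: SensorRecord, path, include_time: bool = True) -> None:
    """Write a sensor record to the package CSV format."""
    cols = {}
    if include_time:
        cols["time"] = np.arange(len(rec)) / rec.fs
    cols.update(ppg=rec.ppg, ax=rec.accel_x, ay=rec.accel_y, az=rec.accel_z)
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.12g")


def read_spc2015_record(path, ref_path=None, ppg_channel: str = "ppg1",
                        rows: Optional[dict] = None,
                        record_id: Optional[str] = None) -> SensorRecord:
    """Read a MATLAB record in the IEEE Signal Processing Cup 2015 layout.

    Parameters
    ----------
    path
        ``.mat`` file containing a 6 x N signal matrix (variable ``sig`` or
        the first 2-D numeric array with 6 rows).
    ref_path
        Optional companion ground-truth file with a BPM vector (variable
        ``BPM0`` or the first numeric vector found).
    ppg_channel
        ``"ppg1"`` (default), ``"ppg2"`` or ``"mean"`` of the two.
    rows
        Override for the row mapping, defaults to :data:`SPC2015_ROWS`.
    """
    rows = dict(SPC2015_ROWS if rows is None else rows)
    try:
        mat = scipy.io.loadmat(path)
    except Exception as exc:  # pragma: no cover - scipy error text varies
        raise IOError(f"cannot read MATLAB file {path}: {exc}") from exc
    sig = _find_matrix(mat, n_rows=6)
    if sig is None:
        raise FormatError(
            f"{path}: expected a 6-row signal matrix (ECG, PPG1, PPG2, "
            "accel x/y/z); none found"
        )
    if ppg_channel == "ppg1":
        ppg = sig[rows["ppg1"]]
    elif ppg_channel == "ppg2":
        ppg = sig[rows["ppg2"]]
    elif ppg_channel == "mean":
        ppg = 0.5 * (sig[rows["ppg1"]] + sig[rows["ppg2"]])
    else:
        raise ValueError(f"unknown ppg_channel {ppg_channel!r}")
    ref_hr = None
    if ref_path is not None:
        ref = scipy.io.loadmat(ref_path)
        vec = _find_vector(ref)
        if vec is None:
            raise FormatError(f"{ref_path}: no ground-truth BPM vector found")
        ref_hr = vec
    return SensorRecord(
        ppg=ppg,
        accel_x=sig[rows["ax"]],
        accel_y=sig[rows["ay"]],
        accel_z=sig[rows["az"]],
        fs=SPC2015_FS,
        ref_hr=ref_hr,
        record_id=record_id if record_id is not None else str(path),
    )


def write_spc2015_record(rec: SensorRecord, path, ref_path=None,
                         ecg: Optional[np.ndarray] = None) -> None:
    """Emit a record in the SPC-2015 ``.mat`` layout (for reader testing).

    The single PPG channel is duplicated into both PPG rows; the ECG row is
    zeros unless given.
    """
    n = len(rec)
    sig = np.zeros((6, n))
    if ecg is not None:
        sig[0] = ecg
    sig[1] = sig[2] = rec.ppg
    sig[3], sig[4], sig[5] = rec.accel_x, rec.accel_y, rec.accel_z
    scipy.io.savemat(path, {"sig": sig})
    if ref_path is not None and rec.ref_hr is not None:
        scipy.io.savemat(ref_path, {"BPM0": rec.ref_hr.reshape(-1, 1)})


def _find_matrix(mat: dict, n_rows: int) -> Optional[np.ndarray]:
    if "sig" in mat:
        sig = np.asarray(mat["sig"], dtype=float)
        if sig.ndim != 2 or sig.shape[0] != n_rows:
            raise FormatError(
                f"signal matrix has shape {sig.shape}; expected {n_rows} rows"
            )
        return sig
    candidates = [
        np.asarray(v) for k, v in mat.items()
        if not k.startswith("__") and isinstance(v, np.ndarray)
    ]
    for arr in candidates:
        if arr.ndim == 2 and arr.shape[0] == n_rows and np.issubdtype(
                arr.dtype, np.number):
            return arr.astype(float)
    # a 2-D numeric array with the wrong number of rows is a layout error
    for arr in candidates:
        if arr.ndim == 2 and np.issubdtype(arr.dtype, np.number) and (
                max(arr.shape) > 1):
            raise FormatError(
                f"signal matrix has shape {arr.shape}; expected {n_rows} rows"
            )
    return None


def _find_vector(mat: dict) -> Optional[np.ndarray]:
    for key in ("BPM0", "BPM", "bpm"):
        if key in mat:
            return np.asarray(mat[key], dtype=float).ravel()
    for k, v in mat.items():
        if k.startswith("__") or not isinstance(v, np.ndarray):
            continue
        arr = np.asarray(v)
        if arr.ndim <= 2 and min(arr.shape, default=0) in (0, 1) and (
                np.issubdtype(arr.dtype, np.number)):
            return arr.astype(float).ravel()
    return None


# ---------------------------------------------------------------------------
# HR trace I/O


def write_hr_trace(trace, path) -> None:
    """Write an HR trace as CSV (window_start_s, window_end_s, hr_bpm, sqt)."""
    if len(trace.estimates) == 0:
        raise ValueError("cannot write an empty HR trace")
    rows = [
        {
            "window_start_s": est.window_start_s,
            "window_end_s": est.window_end_s,
            "hr_bpm": est.hr_bpm,
            "sqt": est.sqt,
        }
        for est in trace.estimates
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")


def read_hr_trace(path, record_id: str = ""):
    """Read an HR trace written by :func:`write_hr_trace`."""
    from .pipeline import HRTrace, WindowEstimate

    df = pd.read_csv(path)
    for col in ("window_start_s", "window_end_s", "hr_bpm", "sqt"):
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} in {path}")
    estimates = [
        WindowEstimate(
            window_start_s=float(r.window_start_s),
            window_end_s=float(r.window_end_s),
            hr_bpm=float(r.hr_bpm),
            sqt=int(r.sqt),
        )
        for r in df.itertuples()
    ]
    return HRTrace(estimates=estimates, record_id=record_id or str(path))
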