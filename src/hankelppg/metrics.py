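"""Agreement metrics between estimated and reference heart rates.

Errors are signed as ``estimate - reference`` (bpm).  Alongside the mean
error, its standard deviation, and the mean absolute error, the Pearson
correlation and Bland-Altman limits of agreement (mean difference
+- 1.96 SD) are reported — the standard panel for validating an HR
estimator against a reference monitor.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.stats


@dataclass
class Metrics:
    """Agreement summary between an HR trace and a reference."""

    me: float  # mean signed error, bpm
    sd: float  # SD of the signed error, bpm
    mae: float  # mean absolute error, bpm
    pearson: Optional[float]  # None when either series is constant
    loa_low: float  # Bland-Altman lower limit of agreement
    loa_high: float
    n_windows: int
    n_sqt0: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def evaluate(est, ref: Sequence[float],
             n_sqt0: Optional[int] = None) -> Metrics:
    """Compare per-window HR estimates with an aligned reference.

    ``est`` may be an :class:`~hankelppg.pipeline.HRTrace` or a plain
    sequence of bpm values; ``ref`` must have one value per window.
    """
    if hasattr(est, "hr_bpm") and not isinstance(est, np.ndarray):
        if n_sqt0 is None:
            n_sqt0 = int(np.sum(est.sqt == 0))
        est_arr = np.asarray(est.hr_bpm, dtype=float)
    else:
        est_arr = np.asarray(est, dtype=float)
    ref_arr = np.asarray(ref, dtype=float)
    if est_arr.shape != ref_arr.shape:
        raise ValueError(
            f"alignment error: {est_arr.size} estimates vs "
            f"{ref_arr.size} reference values"
        )
    if est_arr.size == 0:
        raise ValueError("cannot evaluate an empty trace")
    err = est_arr - ref_arr
    me = float(err.mean())
    sd = float(err.std(ddof=1)) if err.size > 1 else 0.0
    mae = float(np.abs(err).mean())
    if est_arr.size > 1 and est_arr.std() > 0 and ref_arr.std() > 0:
        pearson = float(scipy.stats.pearsonr(est_arr, ref_arr)[0])
    else:
        pearson = None  # undefined for constant series; flagged as None
    return Metrics(
        me=me, sd=sd, mae=mae, pearson=pearson,
        loa_low=me - 1.96 * sd, loa_high=me + 1.96 * sd,
        n_windows=int(est_arr.size), n_sqt0=int(n_sqt0 or 0),
    )
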