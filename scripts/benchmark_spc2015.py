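#!/usr/bin/env python
"""External benchmark on the IEEE Signal Processing Cup 2015 training set.

The dataset is not shipped with this package; download the training
records (DATA_xx_TYPEyy.mat with companion REF_xx_TYPEyy.mat ground-truth
files) and point this script at the directory.  Each record is processed
with the Hankel/SVD pipeline at 8-s windows and a 2-s hop, and the
per-record and pooled agreement metrics against the reference BPM traces
are printed.

Usage:
    python scripts/benchmark_spc2015.py /path/to/spc2015/Training_data
"""

from __future__ import annotations

import argparse
import re
import sys
from pathlib import Path

import numpy as np

import hankelppg as hp


def find_pairs(root: Path):
    for data in sorted(root.glob("DATA_*.mat")):
        ref = data.with_name(re.sub(r"^DATA", "REF", data.name))
        yield data, (ref if ref.exists() else None)


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("root", type=Path,
                        help="directory holding DATA_*.mat / REF_*.mat")
    parser.add_argument("--ppg-channel", default="ppg1",
                        choices=["ppg1", "ppg2", "mean"])
    args = parser.parse_args()

    cfg = hp.PipelineConfig(mar_method="hankel", window_s=8.0, hop_s=2.0)
    all_est, all_ref = [], []
    pairs = list(find_pairs(args.root))
    if not pairs:
        print(f"no DATA_*.mat records under {args.root}", file=sys.stderr)
        return 1
    for data, ref in pairs:
        rec = hp.read_spc2015_record(data, ref_path=ref,
                                     ppg_channel=args.ppg_channel)
        trace = hp.process_record(rec, cfg)
        if rec.ref_hr is None:
            print(f"{data.name}: {len(trace)} windows (no reference)")
            continue
        n = min(len(trace), len(rec.ref_hr))
        est = trace.hr_bpm[:n]
        truth = rec.ref_hr[:n]
        m = hp.evaluate(est, truth)
        print(f"{data.name}: n={n}  ME={m.me:+.2f}  SD={m.sd:.2f}  "
              f"MAE={m.mae:.2f} bpm")
        all_est.append(est)
        all_ref.append(truth)
    if all_est:
        m = hp.evaluate(np.concatenate(all_est), np.concatenate(all_ref))
        r = "undefined" if m.pearson is None else f"{m.pearson:.4f}"
        print(f"\npooled over {m.n_windows} windows: "
              f"ME = {m.me:+.4f} +- {m.sd:.4f} bpm, MAE = {m.mae:.2f} bpm, "
              f"Pearson r = {r}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
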