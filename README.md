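# hankelppg

Heart-rate estimation from motion-corrupted wrist photoplethysmography
(PPG), using a synchronized 3-axis accelerometer as the motion reference.

Wrist-worn optical heart-rate sensors fail exactly when people move: the
optical path between LED and photodetector changes with every arm swing,
and the resulting motion artifact lands at the walking cadence
(1.5-2.5 Hz and harmonics) — right inside the physiological heart-rate
band. `hankelppg` implements a two-stage estimator for this regime:

1. **Signal-quality gating (SQT).** Each analysis window (default 8 s) is
   labelled with a binary Signal Quality Token. A window qualifies only if
   it looks pulsatile: the counts of local maxima and minima differ by at
   most one, consecutive inter-peak intervals t_i satisfy
   |t_{i+1} − t_i| ≤ 0.1·t_i, and the per-cycle kurtosis, mean and
   standard deviation of the detrended, z-normalized window fall inside
   configurable bands. Windows with SQT = 0 are excluded from fresh
   estimation; the previous heart rate is carried forward.

2. **Hankel/SVD motion-artifact removal (MAR).** A qualified window
   x₁,…,x_N is embedded in its Hankel trajectory matrix
   H[i,j] = x_{i+j} (L = ⌈N/2⌉ rows) and decomposed as H = U Σ Vᵀ.
   Each rank-1 component is mapped back to a time series by anti-diagonal
   averaging. Components whose series have absolute Pearson correlation
   ≥ 0.5 with the accelerometer — by default against the dominant
   component series of each axis' own Hankel embedding, which isolates
   every motion harmonic and its spectral quadrature — are flagged as
   motion, and their accelerometer-subspace content is subtracted from
   the window. The cleaned window's heart rate is then the largest
   spectral peak (zero-padded FFT, ≤ 0.5 bpm grid, Hann taper) inside
   0.7-3.5 Hz, subject to a temporal tracking rule: starting from an
   initial estimate of 78 bpm, consecutive estimates may move at most
   10 bpm per window unless no credible peak remains near the previous
   estimate.

A notch-filter MAR variant for hand movement (zero-phase IIR notch at the
cadence detected from the accelerometer spectrum) and a fully seeded
synthetic-data generator with ground truth are included, along with
standard agreement metrics (mean error ± SD, MAE, Pearson correlation,
Bland-Altman limits of agreement).

## Worked example

Estimate heart rate on a 60-s synthetic walking record (true HR 88 bpm,
cadence 1.7 Hz, artifact carrying twice the pulsatile energy):

```python
import hankelppg as hp

params = hp.SynthParams(duration_s=60.0, hr_profile=88.0,
                        motion_freq_hz=1.7, artifact_ratio=2.0, seed=21)
rec, truth = hp.generate(params)

trace = hp.process_record(rec, hp.PipelineConfig(mar_method="hankel"))
m = hp.evaluate(trace, truth.window_hr(8.0, 2.0))
print(f"windows: {m.n_windows}   sqt=0: {m.n_sqt0}")
print(f"ME  = {m.me:+.2f} bpm    SD = {m.sd:.2f} bpm")
print(f"MAE = {m.mae:.2f} bpm")
print(f"LoA = [{m.loa_low:+.2f}, {m.loa_high:+.2f}] bpm")
```

prints

```
windows: 27   sqt=0: 0
ME  = -0.16 bpm    SD = 0.13 bpm
MAE = 0.16 bpm
LoA = [-0.41, +0.10] bpm
```

All 27 overlapping windows qualify and the estimate stays within a
fraction of a beat per minute of the truth. Running the same record with
`mar_method="none"` gives MAE = 13.41 bpm — the untreated estimator locks
onto the 1.7 Hz cadence (102 bpm) instead of the heart rate. The gain
comes entirely from removing the acceleration-correlated subspace before
peak picking.

The same pipeline is available from the shell:

```bash
hankelppg synth --seed 21 --out rec.csv --truth-out truth.csv
hankelppg run --input rec.csv --format csv --mar hankel --out trace.csv
hankelppg eval --trace trace.csv --ref ref.csv --report report.json
```

Records in the IEEE Signal Processing Cup 2015 MATLAB layout (6-row
signal matrix at 125 Hz, optional per-window BPM ground truth) are read
with `--format spc2015` / `hankelppg.read_spc2015_record`; the dataset
itself is not shipped.

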