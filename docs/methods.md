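# Methods

This note documents the model and procedure implemented by `hankelppg`,
the parameter defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the package's known limitations.

## Signal model

A wrist PPG sample stream is modelled as

    x(t) = p(t) + d(t) + a(t) + ε(t)

where `p` is the quasi-periodic pulsatile component synchronized with the
heartbeat, `d` is slow baseline drift from changing tissue absorption and
sensor pressure, `a` is the motion artifact, and `ε` is sensor noise. The
defining assumption of the method is that `a` is *mechanically shared*
with the accelerometer: the same arm motion that perturbs the optical
path also drives the 3-axis acceleration, so the artifact's waveform (a
cadence fundamental plus harmonics) appears, up to per-axis gain and
phase, in both sensors. Nothing else in the PPG is assumed to correlate
with acceleration.

## Stage 1 — signal-quality gating

Each window is linearly detrended and z-normalized, which makes every
subsequent decision invariant under affine amplitude changes
(`assess_quality(c·x + d) == assess_quality(x)` for `c > 0`). Three
checks run in order and short-circuit:

1. **Pulsatility.** Local maxima and minima are detected with a minimum
   spacing of one period of the fastest admissible heart rate and a
   prominence of 0.25 window standard deviations. A pulsatile waveform
   alternates extrema, so the counts may differ by at most one; at least
   3 peaks (`min_beats`) are required so a near-flat window cannot
   qualify.
2. **Interval consistency.** Consecutive inter-peak intervals must agree
   to within a fraction `tol = 0.1`: heart rate drifts slowly relative
   to an 8-s window, so a jump of more than 10% between adjacent
   intervals indicates a misdetected or artifactual peak.
3. **Per-cycle statistics.** For each inter-peak cycle, kurtosis
   (Pearson convention: a Gaussian scores 3, a sinusoid 1.5), mean and
   standard deviation of the normalized window must fall inside accept
   bands. Defaults: kurtosis ∈ [1.0, 4.0], mean ∈ [−0.5, 0.5],
   std ∈ [0.3, 1.7]. These bands are deliberately wide — they reject
   spikes, dropouts and heavy-tailed noise rather than grade waveform
   morphology — and `calibrate_thresholds` can refit them as the
   [1st, 99th] percentile bands of a user's own clean recordings.

The binary label (SQT) gates estimation: windows with SQT = 0 re-emit the
previous heart rate, flagged as carried.

What this gate can and cannot do: it is a *periodicity* test on a single
channel. Incoherent corruption (heavy noise, drift, irregular motion)
reliably fails it. A window dominated by a *coherent* periodic artifact
whose cadence lies inside the heart-rate band is itself periodic and can
pass; rejecting such windows is structurally impossible without consulting
the accelerometer, which is exactly stage 2's job. Consequently the SQT
pass rate is not monotone in artifact-to-signal ratio under a
deterministic harmonic artifact model: balanced mixtures (ratios near
0.5-1) fail most often, while artifact-dominated windows pass more often
than mixtures. The acceptance suite measures this honestly and the
corresponding discrimination clauses are expected to fail under the
synthetic walking model; see Limitations.

## Stage 2 — Hankel/SVD motion-artifact removal

An N-sample window is embedded into the Hankel trajectory matrix with
L = ⌈N/2⌉ rows and K = N − L + 1 columns, `H[i, j] = x[i+j]` — the
standard singular-spectrum-analysis embedding, covering every sample so
that full-rank reconstruction is exact. The SVD `H = U Σ Vᵀ` splits the
window into r = min(L, K) rank-1 components; anti-diagonal averaging
(Hankelization) maps each back to a series. Implementation note: the
anti-diagonal sums of the outer product `u vᵀ` equal the linear
convolution `u * v`, so all r component series are produced by one
batched FFT convolution rather than r matrix materializations.

**References.** The three acceleration axes are decomposed the same way,
and the correlation test runs against the dominant component series of
each axis (smallest leading set capturing 99.9% of squared singular
mass, at most 8 per axis). This matters for two reasons: (i) the two
elementary series of a tone are parallel to the tone itself, so each
axis decomposition yields every motion harmonic as a clean reference
tone regardless of phase; (ii) correlating against the raw composite
axis instead dilutes per-harmonic correlation by the axis' total energy
(a 2nd harmonic carrying 18% of axis energy correlates at only ~0.43
with the raw axis, below threshold, but at ~1.0 with its own component).
Correlating against the raw axes remains available
(`correlation_mode="raw_accel"`).

**Selection.** A PPG component is flagged as motion iff its maximum
absolute Pearson correlation against the references reaches
`threshold = 0.5`, strongest first, up to `max_remove` (default r − 1);
at least one component is always kept. A zero-variance reference (flat
accelerometer) defines correlation 0, so motionless records are passed
through untouched.

**Removal.** By default (`removal="projection"`), each flagged
component sheds its least-squares projection onto the span of the
reference series rather than being dropped wholesale. For a genuine
motion component the correlation is ≈ 1 and the two are identical. The
difference matters when the beat and a motion tone have nearly equal
singular values: the SVD basis of a near-degenerate subspace is
arbitrary, so a single component can carry a mixture of both, and
dropping it wholesale destroys beat energy. Projection removal excises
exactly the accelerometer-explainable content and returns the remainder
to the window. Wholesale removal is available as `removal="full"`.

## Spectral estimation and tracking

The cleaned window is zero-meaned, Hann-tapered, zero-padded to a
≤ 0.5 bpm frequency grid, and transformed; the heart rate is
60 × the frequency of the largest magnitude peak inside the HR band
(default 0.7-3.5 Hz = 42-210 bpm, slightly wider than the 1-4 Hz
physiological quote so resting bradycardia is admissible), refined by
parabolic interpolation. The Hann taper is load-bearing: rectangular
windowing leaves first sidelobes at ~22% of the main peak, big enough to
be mistaken for a credible secondary peak by the tracking rule below;
Hann sidelobes (−31 dB) are not.

Tracking: the first window's reference is `init_hr = 78` bpm; each
subsequent search is confined to ±`max_jump_bpm = 10` around the
previous estimate. The confined choice must be a genuine local peak — a
band-edge argmax whose magnitude is still rising outward is the skirt of
an out-of-band peak and does not count — with magnitude at least
`rel_floor = 0.2` of the global band maximum; otherwise tracking is
abandoned for the window (flagged `tracked=False`) and the global argmax
is used. Ties break toward the lower frequency. When the tracking band
leaves the HR band entirely, the previous estimate is carried forward.

## Notch-filter variant (hand movement)

For micro-motions the dominant cadence is read off the summed
accelerometer magnitude spectra in 0.5-5 Hz (flat spectra — peak below
3× the in-band median — are treated as "no motion" and leave the PPG
untouched) and removed with a zero-phase second-order IIR notch
(`Q = 5`), optionally at harmonics. This path trades the subspace
machinery for a fixed spectral surgery and is appropriate when the
artifact is narrowband and well-separated from the heart rate.

## Pipeline

Records are band-pass filtered once (0.4-10 Hz, zero-phase Butterworth,
order 3) — the per-cycle statistics are meaningless on top of large DC
drift — then processed in 8-s windows with a 2-s hop. Determinism: the
pipeline is a pure function of (record, config); identical inputs give
bit-identical traces.

## Synthetic-data generator

`synth.generate` emulates the structure the method assumes, with every
amplitude expressed relative to the pulsatile RMS:

| parameter | default | meaning |
|---|---|---|
| `fs` | 125 Hz | sampling rate (SPC-2015 convention) |
| `hr_profile` | 72 bpm | constant or piecewise-linear HR, 40-180 bpm |
| `pulse_shape` | (1.0, 0.4, 0.15) | beat-template harmonic amplitudes |
| `motion_freq_hz` | 2.0 | walking cadence |
| `motion_harmonics` | 3 | harmonics at gains 1/h, random phases |
| `artifact_ratio` | 0 | artifact RMS / pulsatile RMS |
| `drift_amp` | 0.3 | drift RMS (noise low-passed at 0.15 Hz) |
| `noise_sd` | 0.05 | white-noise SD |
| `accel_coupling` | (1.0, 0.6, 0.3) | per-axis artifact gain |
| `accel_noise_sd` | 0.01 | accelerometer's own noise, vs artifact RMS |

Defaults were chosen once as a plausible wrist-worn walking scenario: a
beat template whose harmonics decay like a real PPG pulse, drift below
0.15 Hz as seen in raw wrist traces, a few percent sensor noise, and a
1% accelerometer noise floor so correlations are near-but-not-exactly
±1 and the threshold logic is actually exercised. The generator is
fully deterministic given its seed, returns the clean pulsatile series
and per-sample true HR, and `generate_batch` derives independent
per-record seeds (< 2³¹) from one master seed.

What it does **not** emulate: stride-to-stride cadence variability and
amplitude modulation of real gait, sensor saturation and contact loss,
morphological beat changes (dicrotic notch variation, arrhythmia), or
any optical tissue physics. Passing the synthetic acceptance properties
therefore demonstrates correct mechanics of the algorithm under its own
assumptions, not clinical accuracy; validation on real recordings (e.g.
the IEEE SPC 2015 training set, readable via `read_spc2015_record`)
remains an external benchmark.

## Problem sizes used by the acceptance computations

The acceptance suite and `scripts/acceptance.py` use: 500 random series
(lengths 4-400) for the embedding round-trip; 100 random windows for SVD
completeness; 200 series of length ≤ 12 against loop-based oracles; a
100-record walking batch (20-s records, i.e. 7 overlapping windows each;
HR ~ U(60, 100) bpm, cadence ~ U(1.5, 2.5) Hz, artifact ratio 2) for
pipeline recovery; 200 windows per artifact ratio in {0, 0.5, 1, 2, 5}
for gate discrimination; 20 hand-movement records (HR 72 bpm, motion
2.4 Hz) for the notch variant; the exhaustive 71³ grid of 3-interval
combinations (0.01-s steps over [0.5, 1.2] s) for the interval rule.

## Numerical choices

- Hankelization returns the anti-diagonal value directly wherever the
  anti-diagonal is constant, so `hankelize(build_hankel(x)) == x` bit
  for bit; averaging would be one ulp off.
- Kurtosis uses the biased fourth-standardized-moment estimator
  (`excess=False`), configurable to the excess convention.
- Cycle segmentation is peak-to-peak; valley-to-valley is a flag.
- Pearson correlation with a zero-variance input is defined as 0.
- `pick_hr` ties break toward the lower frequency; interpolated peak
  positions are clamped back into the tracking band.
- The SPC-2015 reader assumes the public channel order (ECG, two PPG,
  three accelerations); the row mapping is overridable.

## Known limitations

- **Cadence–heart-rate collision.** When |f_HR − f_cadence| falls below
  roughly 0.15 Hz, an 8-s window cannot distinguish the two tones: the
  beat's components correlate with the accelerometer references almost
  as strongly as the artifact's, removal damages the fundamental, and
  its orthogonal residue splits into sidebands ±~0.1 Hz around the true
  rate. Per-window errors of 3-8 bpm (or a lock onto the beat's 2nd
  harmonic) are then expected. In the 100-record walking batch these
  collision records are the dominant error source; the within-±2 bpm
  fraction of qualified windows sits at ~90% (89.95% at the committed
  batch seed, 93-95% at neighbouring seeds).
- **Coherent in-band artifacts pass the quality gate** (see Stage 1):
  the gate's pass rate is non-monotone in artifact ratio and
  artifact-dominated windows are not reliably rejected. The pipeline
  still handles them — stage 2 removes what stage 1 cannot see — but
  the gate alone must not be read as an artifact detector.
- **Carried windows inherit tracking state.** Records whose early
  windows all fail the gate emit the 78 bpm initialization until a
  window qualifies; batch MAE therefore mixes estimation error with
  gating behaviour.
- The notch variant assumes a narrowband, stationary cadence within the
  window and at least ~0.2 Hz separation from the heart rate.
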