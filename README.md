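# physiofuse

A desk-scale toolkit for building and validating multi-device physiological
monitoring pipelines of the kind used in diver and field biosensor studies:
heterogeneous-rate sensor streams (ECG at 200 Hz, optical tissue oximetry at
~38 Hz and 0.5 Hz, device-reported heart rate at ~1 Hz) fused onto a single
master clock, reconciled with onboard cached copies after wireless dropouts,
turned into heart-rate and oxygenation estimates, and scored for
between-device agreement — plus an 8-channel Simon-task EEG pipeline for
error-related theta analysis.

Because study recordings of this kind are rarely shareable, the package
ships a first-class **synthetic session generator** that emulates the
statistical structure of every input (protocol-driven HR trajectories,
template ECG, occlusion desaturation kinetics, device bias/lag/jitter/
dropout, BLE gaps with clock-offset cached copies, Simon-task EEG with
blinks and error-trial theta bursts) together with a ground-truth sidecar,
so every stage of the pipeline is testable end to end.

## What it computes

- **Master-clock fusion** (`fusion`): sample-and-hold up-sampling onto a
  200 Hz tick grid; each cell is the latest valid sample of its stream with
  a per-cell freshness flag (fresh / held / missing); lossless HDF5
  round-trip; `deduplicate_held` inverts the placeholder expansion.
- **Cached-data alignment** (`alignment`): normalized cross-correlation lag
  estimation with sub-sample parabolic refinement, affine clock maps
  (offset + optional drift), and piecewise gap patching that never alters a
  streamed sample.
- **ECG → HR** (`cardio`): Pan-Tompkins-style R-peak detection (band-pass,
  derivative energy, adaptive threshold, 250 ms refractory), IBI →
  instantaneous HR = 60/IBI, centered 100-beat rolling mean, per-phase
  quality reports (sensitivity/PPV against ground truth at ±50 ms).
- **Device agreement** (`agreement`): co-resampling to a shared 10 Hz grid,
  Pearson r, Bland-Altman analysis — bias = mean(a−b), limits of agreement
  bias ± 1.96·SD(a−b), proportional-bias slope from OLS of difference on
  pair mean — phase-progress normalization (500 points/phase) and
  occlusion normalization (cubic, 1,000 frames/min), group mean ± SEM.
- **StO2 QC** (`oximetry`): plausibility filtering (<5 %, >95 %, or >20
  percentage-point jump from the last accepted sample), rejection rates,
  placement error vs a reference site.
- **EEG pipeline** (`eeg`): 0.1–30 Hz zero-phase Butterworth, blink-segment
  ICA with weight transfer to the continuous data, −1,000..1,500 ms epochs,
  100 µV voltage and 50 dB (20–40 Hz) spectral rejection, channel exclusion
  at >20 % bad epochs with spherical-spline interpolation, participant
  exclusion at >10 % interpolated channels, single-trial complex-Morlet
  time-frequency (2–30 Hz in 20 linear steps, 3–6 cycles log-spaced) with
  divisive dB baseline (−400..−100 ms, stimulus-locked), and Simon-task
  trial classification (500 ms response window, late/missed exclusion).

## Worked example

```python
import physiofuse as pf
from physiofuse.synth import generate_session

sess = generate_session(protocol="exercise", seed=7)
ecg, cached = sess.streams["nps/ecg"], sess.cached["nps/ecg"]

lag = pf.estimate_lag_xcorr(ecg, cached, max_lag_s=10.0, fs_hz=200.0)
patched = pf.patch_gaps(ecg, cached, pf.fit_clock_map(lag=lag))
beats = pf.detect_rpeaks(patched.stream, fs_hz=200.0)
hr = pf.smooth_hr(beats)
_, a, b = pf.crop_and_resample(hr, sess.streams["polar/hr"], sess.timeline, rate_hz=10.0)
res = pf.bland_altman(a, b)
```

Output of the session above:

```
estimated clock offset: 2.5000 s (injected 2.5 s), peak correlation 0.955
patched 6000 cached samples into 1 gap(s)
1100 R-peaks detected
Pearson r = 0.997 (n = 7171)
bias = -0.20 bpm, LOA = [-5.22, 4.82] bpm, proportional-bias slope = -0.0271
```

The injected 2.5 s clock offset of the cached ECG copy is recovered to
sub-millisecond precision, the 30 s BLE gap is refilled exactly (6,000
samples at 200 Hz), and the ECG-derived HR agrees with the simulated
chest-strap HR with near-zero bias: the simulated devices share one
ground-truth heart rate, so residual spread reflects only the injected
jitter and the strap's 2 s response lag.

## Command line

```bash
physiofuse simulate --protocol occlusion --seed 1 --out session/
physiofuse fuse --rate 200 --streams session/polar_hr.csv --out session.h5
physiofuse align --ref session/nps_ecg.csv --cached session/nps_ecg_cached.csv --out patched.csv
physiofuse hr --in patched.csv --out hr.csv
physiofuse agree --a hr.csv --b session/polar_hr.csv --events session/events.json --out report.json
physiofuse sto2-qc --in session/nps_sto2.csv --ref session/moxy_sto2.csv --out qc.json
physiofuse run --protocol exercise --seed 42 --out demo/   # full chain + manifest
```

`run` chains simulate → fuse → align → hr → agree → sto2-qc → eeg and writes
a manifest with SHA-256 checksums of every artifact; the same config and
seed always reproduce byte-identical outputs.

## Documentation

`docs/methods.md` describes the models behind the synthetic generator, the
numerical choices in each pipeline stage, and known limitations.
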