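# Methods

This note documents the models, parameter choices and numerical decisions
behind the package, and what the synthetic-data tests do and do not
establish about real recordings.

## Synthetic sessions

The generator's job is to reproduce the *statistical structure* the
pipeline assumes — not the physiology. All randomness in a session flows
from one seeded generator, so a seed fully determines a session
(bit-identical regeneration is tested).

**Protocols.** Two built-in templates mirror common validation designs: a
graded vaso-occlusive ramp (3 min baseline, 1 min each at 100/150/200 mmHg,
5 min recovery; 660 s) and an exercise ramp (2 min rest, 2 min each at
50–60 %, 60–70 %, 70–80 % of HRmax, 4 min recovery; 720 s).

**Heart rate.** HR(t) relaxes toward each phase's target (the midpoint of
the prescribed %HRmax zone, or resting HR) as a first-order exponential
with time constant `tau_s` (default 30 s — a typical on-kinetics value for
moderate exercise), continuous at phase boundaries and clipped to
30–220 bpm. Beats are placed by integrating the instantaneous rate
(time-warping): the cumulative beat phase crosses successive integers at
the beat times, which makes HR(t) exactly recoverable from the inter-beat
intervals — the property the cardio pipeline is scored against.

**ECG.** Each beat contributes a stereotyped complex built from Gaussian
bumps (Q −0.10, R +1.00, S −0.15, T +0.25 mV at 8–60 ms widths). This is a
template model, sufficient for exercising band-pass + adaptive-threshold
R-peak detection; it does not capture morphology changes (axis shifts,
ectopy, electrode artifacts) beyond additive noise. Motion/immersion
degradation is modeled as broadband noise plus 0.15–0.4 Hz baseline wander
scaled by a per-segment degradation factor; these factors are free
parameters, not calibrated to any device.

**Reported-metric devices.** A device channel is the ground-truth
trajectory sampled at the device rate after a response lag, plus a constant
bias and white jitter, with i.i.d. per-sample dropout. Defaults (1 Hz,
bias ≤ 1 bpm, lag 2–4 s, jitter 1–1.5 bpm, 1 % dropout) are plausible for
chest straps and fingertip oximeters.

**BLE dropouts and cached copies.** The streamed copy loses all samples in
configurable dropout intervals (default one 30 s mid-session gap); the
cached copy is complete but time-shifted by a constant clock offset
(default 2.5 s). Clock drift is not injected by default but the alignment
module can fit it from anchor pairs.

**StO2.** Baseline plateau (65 %), linear desaturation during occlusion at
`0.10 %/min per mmHg` (so 100→200 mmHg doubles the slope by construction),
and exponential recovery (tau 30 s) plus a reperfusion-hyperaemia overshoot
shaped as an alpha function (5 % peak at 20 s). Values are clipped to
[0, 100] after noise.

**Simon-task EEG.** Eight channels (Fz, C3, Cz, C4, Pz, PO7, Oz, PO8) at
250 Hz. The background is six shared pink-noise sources mixed through a
fixed random topography plus 15 % independent sensor noise — spatial
sharing matters: with fully independent per-channel noise the recording has
more effective sources than channels and blink-ICA separation is impossible
in principle, which misrepresents real scalp data. On top: 10 Hz posterior
alpha with slow amplitude modulation, frontal-dominant 300 ms raised-cosine
blink transients (steep ocular falloff: Fz 1.0 → posterior 0.02; ~80 µV at
Fz, ~0.15/s with 1 s refractory), and — on error trials only — a 6 Hz,
8 µV Hann-windowed theta burst 0–400 ms post-response with a Cz-centered
midline topography. Behavioral timing follows the task protocol: 200 ms
stimulus, 500 ms response window, RSI jittered 800–1,200 ms, 160
trials/block; RTs are log-normal (median ≈ 330 ms) truncated to the window,
with configurable late-response (2 %) and miss (1 %) probabilities and a
10 % error rate.

What passing tests on these sessions show: the pipeline recovers known
injected structure under realistic rates, noise levels and artifact
topographies. What they do not show: robustness to non-stationary real
artifacts (electrode pops, sweat drift, EMG), to morphology pathology, or
to device firmware quirks.

## Fusion

The master clock ticks exactly `round(1e9 / rate)` ns apart — integer
nanoseconds, so there is no accumulated drift. A cell holds the latest
*valid* sample at or before its tick (a sample exactly on a tick belongs to
that tick); it is flagged *fresh* when that sample arrived within the last
tick interval, *held* otherwise, and *missing* before a stream's first
sample — missing is never back-filled, since that would invent
pre-acquisition data. No interpolation is ever performed, which is what
makes `deduplicate_held` an exact inverse (up to tick quantization of the
timestamps). Rate ratios are handled purely by timestamp comparison, never
index arithmetic, because device rates are nominal. The default grid ends
one tick past the last sample so every sample is covered regardless of grid
phase.

## Alignment

Lag estimation resamples both streams to a common grid (default 200 Hz),
removes means, and maximizes normalized cross-correlation within the search
window, then refines the peak by parabolic interpolation of the three
surrounding correlation values — normalization makes the estimate invariant
to amplitude scaling between streamed and cached copies, and the refinement
takes the error well below one grid sample. The overlap must exceed twice
the search window; flat signals are rejected. Periodic signals can in
principle alias the lag by one period; varying-rate content (an exercise
ramp) disambiguates, which is why the default correlation segment should
contain rate variation or be restricted to a known-good window. A gap is an
inter-sample interval above 3× the nominal period; cached samples are
inserted only strictly inside gaps, half a period clear of the edges, so a
sub-sample clock-map error cannot duplicate edge samples. Streamed samples
are never modified.

## Cardio

The detector is a Pan-Tompkins-style chain: 8–20 Hz band-pass (order 3,
zero-phase), derivative, squaring, 150 ms moving integration, candidate
peaks at ≥250 ms spacing, adaptive threshold at 30 % of the rolling
(21-candidate) upper-decile energy — the upper decile tracks QRS energy
even when most candidates between beats are noise, and the ratio form makes
detection invariant to amplitude scaling. Peaks are refined to the
band-passed maximum within ±100 ms; amplitudes are read from the raw
signal. Detections within 200 ms of the record edges are discarded
(truncated complexes). IBis outside 0.27–2.0 s (30–220 bpm) are flagged
implausible; ectopic flags mark IBIs deviating >20 % from the local 11-beat
median.

The 100-beat centered rolling mean uses shrinking windows at the edges
(minimum 1). One caveat documented deliberately: a centered moving average
is biased upward on convex decaying segments (e.g. post-exercise recovery),
by the factor sinh(h/τ)/(h/τ) on an exponential with time constant τ
averaged over half-width h. At resting HR the 100-beat window spans ~100 s,
so this bias reaches several bpm in recovery regardless of detection
quality. HR-recovery checks therefore compare the estimate against the
ground-truth instantaneous HR at the true beat times *pushed through the
same smoothing operator*, which isolates detection error from this known
operator bias.

Device-reported HR/PR values are consumed as-is and never recomputed.

## Agreement

The shared 10 Hz grid is inclusive of the start tick and half-open at the
end (60 s → 600 pairs); pairs where either stream lacks coverage are
dropped. Bland-Altman uses the n−1 SD, LOAs at ±1.96 SD, and OLS of
difference on pair mean for proportional bias. Pooled analyses concatenate
across subjects/repetitions; pooling repeated measures understates LOA
uncertainty, so a per-subject stratified mode exists. SEM uses the n−1 SD;
SEM with a single subject is reported as NaN. Occlusion normalization
resamples each phase to 1,000 frames per *nominal* minute with cubic
splines (11,000 frames for the standard template); cubic interpolation
preserves constants exactly and its overshoot on monotone inputs is bounded
in tests at 1 % of range.

## StO2 QC

The jump rule compares against the last *accepted* sample, so one spike
cannot cascade into rejecting the rest of the trace. Each rejected sample
gets a single primary reason with precedence low > high > jump; reason
counts therefore sum to the rejection count. The jump rule is per-sample
(device rates differ; a per-unit-time variant would need a rate argument)
and the threshold is configurable. Placement error is reported both as
signed mean (bias direction) and mean absolute (magnitude) percent
difference; reference-zero ticks are excluded and counted.

## EEG

Filtering is a 4th-order zero-phase Butterworth band-pass (0.1–30 Hz); the
0.1 Hz edge implies ~10 s edge transients, which the epoch windows never
reach in practice. Blink detection thresholds the ≤4 Hz frontal channel at
median + 4·MAD (SD-scaled), minimum separation 500 ms. Blink-segment ICA
(FastICA, 8 components, fixed random state for reproducibility) is fitted
on concatenated ±500 ms windows around blinks, where the blink source
dominates; the component maximizing correlation with the low-passed frontal
channel within segments is removed from the *full* recording via the
segment-learned unmixing. With only 8 channels some background leakage into
the blink component is unavoidable; tests bound it via alpha-power
preservation (<10 % change) while requiring ≥80 % blink-band power
reduction.

Spectral rejection is defined concretely as mean Welch PSD in 20–40 Hz in
dB re 1 µV²/Hz, with voltage checked before spectrum so each flag has one
reason. The participant-exclusion rule is applied literally: with 8
channels, any interpolated channel (12.5 %) exceeds the 10 % limit; the
thresholds are parameters for montage-aware variants. Spherical-spline
channel reconstruction uses order-4 splines on standard 10–20 positions
(via mne).

The Morlet transform uses unit-energy complex wavelets, 20 linear
frequencies 2–30 Hz with cycle counts log-spaced 3→6, convolution per
single trial; output is decimated in time (default 5× → 50 Hz) because
band power varies slowly relative to the raw rate, and samples within one
wavelet half-length of an epoch edge are flagged unreliable. Note 16 Hz is
exactly equidistant between two grid bins (15.26, 16.74 Hz); tests treat
either neighbor as "nearest". Baseline normalization is divisive and
single-trial: every epoch of trial N (stimulus- or response-locked) is
divided by the mean power of trial N's stimulus-locked epoch in
−400..−100 ms, then scaled 10·log10; condition averages are taken after
per-trial normalization.

## Problem sizes

Default test and acceptance runs use one 720 s exercise session (≈1,100
beats), 30–100 seeded alignment sessions, one 160-trial EEG block per
condition, and 20–50 random fusion sessions of ≤10 s — sizes chosen so the
whole suite completes in a few minutes on a single core while every check
retains comfortable statistical margin.

## Known limitations

- The generator is phenomenological throughout: no cardiovascular or
  hemodynamic mechanism, no pressure/immersion physiology beyond
  degradation factors, no EEG forward model.
- ECG "artifact correction" here is the declared plausibility/ectopy
  flagging; it is not claimed identical to any external library's cleaning.
- Cross-correlation alignment assumes an (approximately) affine clock
  relation; nonlinear clock warping is out of scope.
- Agreement numbers produced on synthetic sessions are demonstrations of
  the machinery, not reproductions of any human-subject result.
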