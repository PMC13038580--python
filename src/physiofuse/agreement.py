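"""Between-device agreement statistics.

Pairs of HR (or other metric) streams are cropped to the experiment
interval and co-resampled onto a shared 10 Hz grid by linear
interpolation; agreement is then quantified by Pearson correlation and
Bland-Altman analysis: bias = mean paired difference, limits of agreement
(LOA) = bias +/- 1.96 x SD of the differences, and a proportional-bias
slope from ordinary least squares of the difference on the pair mean.
Phase-progress normalization maps variable-duration protocol phases onto
fixed-length grids so curves can be averaged across subjects (mean +/-
SEM), and occlusion traces are resampled cubically at 1,000 frames per
nominal protocol minute.

Pooled analyses concatenate pairs across subjects and repetitions; note
that pooling repeated measures understates the uncertainty of the LOAs, so
a per-subject stratified mode is also provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate, stats

from .protocol import EventTimeline
from .streams import NS_PER_S, TimestampedStream


@dataclass
class PhaseNormalizedSeries:
    """Per-phase values on fixed-length progress grids (0 -> 1)."""

    phase_labels: tuple[str, ...]
    values: dict                       # phase -> array
    progress: dict                     # phase -> grid in [0, 1]
    subject_id: str = ""
    device_id: str = ""

    def concatenated(self) -> np.ndarray:
        return np.concatenate([self.values[p] for p in self.phase_labels])

    @property
    def total_frames(self) -> int:
        return sum(len(self.values[p]) for p in self.phase_labels)


@dataclass(frozen=True)
class AgreementResult:
    n: int
    pearson_r: float
    pearson_p: float
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    prop_bias_slope: float
    #: plot payload: paired means and differences
    means: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    diffs: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def to_dict(self) -> dict:
        return {
            "n": self.n, "pearson_r": self.pearson_r, "pearson_p": self.pearson_p,
            "bias": self.bias, "sd_diff": self.sd_diff,
            "loa_low": self.loa_low, "loa_high": self.loa_high,
            "prop_bias_slope": self.prop_bias_slope,
        }


def crop_and_resample(
    a: TimestampedStream,
    b: TimestampedStream,
    timeline: EventTimeline,
    rate_hz: float = 10.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Both streams linearly interpolated onto one shared grid.

    The grid covers the timeline half-open, inclusive of the start tick:
    ``t0, t0 + 1/rate, ...`` up to but excluding the end.  Grid points
    outside either stream's own coverage are dropped (pair-level missing
    data exclusion).  Returns ``(t_s, a_vals, b_vals)``.
    """
    av, bv = a.only_valid(), b.only_valid()
    if not len(av) or not len(bv):
        raise ValueError("empty stream")
    t0 = timeline.start_ns / NS_PER_S
    t1 = timeline.end_ns / NS_PER_S
    n = int(np.floor((t1 - t0) * rate_hz))
    grid = t0 + np.arange(n) / rate_hz
    at, bt = av.times_s, bv.times_s
    cover = (grid >= max(at[0], bt[0])) & (grid <= min(at[-1], bt[-1]))
    if not cover.any():
        raise ValueError("streams do not overlap on the timeline")
    g = grid[cover]
    return g, np.interp(g, at, av.values), np.interp(g, bt, bv.values)


def _phase_resample(
    stream: TimestampedStream, timeline: EventTimeline,
    points_for_phase, method: str,
) -> PhaseNormalizedSeries:
    sv = stream.only_valid()
    t = sv.times_s
    labels, values, progress = [], {}, {}
    for ev in timeline:
        lo, hi = ev.start_ns / NS_PER_S, ev.end_ns / NS_PER_S
        n_pts = points_for_phase(ev)
        grid = np.linspace(0.0, 1.0, n_pts)
        sample_t = lo + grid * (hi - lo)
        m = (t >= lo - 1e-9) & (t <= hi + 1e-9)
        tt, vv = t[m], sv.values[m]
        if len(tt) < 2:
            raise ValueError(f"phase {ev.label}: not enough samples to resample")
        if method == "linear":
            out = np.interp(sample_t, tt, vv)
        elif method == "cubic":
            if len(tt) >= 4:
                f = interpolate.CubicSpline(tt, vv)
                out = f(np.clip(sample_t, tt[0], tt[-1]))
            else:
                out = np.interp(sample_t, tt, vv)
        else:
            raise ValueError(f"unknown method {method!r}")
        labels.append(ev.label)
        values[ev.label] = out
        progress[ev.label] = grid
    return PhaseNormalizedSeries(
        phase_labels=tuple(labels), values=values, progress=progress,
        subject_id="", device_id=stream.device_id,
    )


def normalize_phase_progress(
    stream: TimestampedStream,
    timeline: EventTimeline,
    n_points: int = 500,
    method: str = "linear",
) -> PhaseNormalizedSeries:
    """Map each phase onto a normalized progress axis of ``n_points`` samples.

    Subjects with different phase durations produce identical shapes,
    enabling element-wise averaging; endpoints are interpolated at the
    exact phase boundaries.
    """
    return _phase_resample(stream, timeline, lambda ev: n_points, method)


def normalize_occlusion(
    stream: TimestampedStream,
    timeline: EventTimeline,
    frames_per_min: int = 1000,
    method: str = "cubic",
) -> PhaseNormalizedSeries:
    """Occlusion-trace normalization at ``frames_per_min`` x nominal minutes.

    With the standard five-phase occlusion protocol (3 + 1 + 1 + 1 + 5
    minutes) this yields 11,000 frames total, cubically interpolated.
    """
    def pts(ev):
        return int(round(frames_per_min * ev.duration_s / 60.0))
    return _phase_resample(stream, timeline, pts, method)


def pearson_agreement(a: np.ndarray, b: np.ndarray) -> tuple[float, float, int]:
    """Product-moment correlation with two-sided p; returns (r, p, n)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("need >= 3 paired samples")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p), len(a)


def bland_altman(a: np.ndarray, b: np.ndarray) -> AgreementResult:
    """Bland-Altman agreement of paired series ``a`` and ``b``.

    bias = mean(a - b); LOAs = bias +/- 1.96 x SD(a - b) (n-1 denominator);
    proportional-bias slope = OLS slope of (a - b) on (a + b) / 2.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("need >= 3 paired samples")
    diffs = a - b
    means = 0.5 * (a + b)
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    var_m = means.var(ddof=1)
    slope = float(np.cov(means, diffs, ddof=1)[0, 1] / var_m) if var_m > 0 else 0.0
    r, p = (stats.pearsonr(a, b) if np.std(a) > 0 and np.std(b) > 0 else (np.nan, np.nan))
    return AgreementResult(
        n=len(a), pearson_r=float(r), pearson_p=float(p),
        bias=bias, sd_diff=sd,
        loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd,
        prop_bias_slope=slope, means=means, diffs=diffs,
    )


def stratified_bland_altman(pairs_by_subject: dict) -> dict:
    """Per-subject Bland-Altman results (pooling caveat: see module docs)."""
    return {sid: bland_altman(a, b) for sid, (a, b) in pairs_by_subject.items()}


def group_mean_sem(
    series: list[PhaseNormalizedSeries],
) -> tuple[dict, dict, dict]:
    """Element-wise mean and SEM across subjects on the shared grids.

    Returns ``(mean, sem, n)`` dicts keyed by phase.  SEM uses the n-1
    denominator SD; with a single subject SEM is NaN (flagged missing).
    Subjects missing a phase simply do not contribute to its n.
    """
    if not series:
        raise ValueError("no series")
    phases = series[0].phase_labels
    mean, sem, ns = {}, {}, {}
    for ph in phases:
        stack = np.stack([s.values[ph] for s in series if ph in s.values])
        n = stack.shape[0]
        mean[ph] = stack.mean(axis=0)
        sem[ph] = (
            stack.std(axis=0, ddof=1) / np.sqrt(n) if n > 1
            else np.full(stack.shape[1], np.nan)
        )
        ns[ph] = n
    return mean, sem, ns


def plot_bland_altman(result: AgreementResult, ax=None, title: str = ""):
    """Difference-vs-mean scatter with bias and LOA reference lines."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(result.means, result.diffs, s=4, alpha=0.4)
    for y, style in ((result.bias, "-"), (result.loa_low, "--"), (result.loa_high, "--")):
        ax.axhline(y, color="k", linestyle=style, linewidth=1)
    ax.set_xlabel("pair mean")
    ax.set_ylabel("difference")
    if title:
        ax.set_title(title)
    return ax
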