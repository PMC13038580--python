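"""Reconciling cached onboard recordings with the reference timeline.

Devices that lose telemetry (e.g. underwater BLE dropouts) keep a complete
onboard copy of their data, but on their own clock.  This module estimates
the clock offset between a cached copy and the synchronized reference by
normalized cross-correlation with sub-sample parabolic refinement, fits an
affine device-to-reference clock map (offset, optional drift), and patches
transmission gaps in the streamed record with re-timestamped cached
samples — never altering any streamed sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .streams import NS_PER_S, TimestampedStream, s_to_ns


class InsufficientOverlapError(ValueError):
    pass


class UndefinedCorrelationError(ValueError):
    pass


@dataclass(frozen=True)
class LagEstimate:
    """Estimated clock offset of the cached copy relative to the reference.

    ``lag_s`` is positive when the cached clock is ahead (cached timestamps
    = reference + lag).  ``peak_corr`` is the normalized correlation at the
    optimum and serves as a confidence score.
    """

    lag_s: float
    peak_corr: float
    search_window_s: float
    segment_used: tuple[int, int]

    def __post_init__(self):
        if abs(self.lag_s) > self.search_window_s + 1e-9:
            raise ValueError("lag outside search window")


@dataclass(frozen=True)
class ClockMap:
    """Affine device-to-reference time map.

    ``reference_ns = slope * device_ns + intercept_ns`` with
    ``slope = 1 / (1 + drift_ppm * 1e-6)``.  With a single lag estimate the
    drift is zero and the map is a pure offset.
    """

    offset_s: float
    drift_ppm: float = 0.0
    fit_pairs: tuple = field(default_factory=tuple)

    @property
    def slope(self) -> float:
        return 1.0 / (1.0 + self.drift_ppm * 1e-6)

    def apply_ns(self, device_ns: np.ndarray) -> np.ndarray:
        dev = np.asarray(device_ns, dtype=np.int64)
        ref = self.slope * (dev.astype(float) - self.offset_s * NS_PER_S)
        return np.round(ref).astype(np.int64)

    def invert_ns(self, reference_ns: np.ndarray) -> np.ndarray:
        ref = np.asarray(reference_ns, dtype=np.int64)
        dev = ref.astype(float) / self.slope + self.offset_s * NS_PER_S
        return np.round(dev).astype(np.int64)


def estimate_lag_xcorr(
    ref: TimestampedStream,
    cached: TimestampedStream,
    max_lag_s: float = 30.0,
    fs_hz: float = 200.0,
    segment: tuple[float, float] | None = None,
) -> LagEstimate:
    """Clock offset of ``cached`` vs ``ref`` by normalized cross-correlation.

    Both streams are resampled internally onto a common ``fs_hz`` grid over
    the overlap of their spans (restricted to ``segment`` seconds if given,
    e.g. a pre-baseline window of stable transmission), mean-removed, and
    cross-correlated; the peak within +/-``max_lag_s`` is refined to
    sub-sample precision by parabolic interpolation of the three
    correlation values around it.
    """
    r, c = ref.only_valid(), cached.only_valid()
    t_lo = max(r.timestamps[0], c.timestamps[0] - s_to_ns(max_lag_s))
    t_hi = min(r.timestamps[-1], c.timestamps[-1] + s_to_ns(max_lag_s))
    if segment is not None:
        t_lo = max(t_lo, s_to_ns(segment[0]))
        t_hi = min(t_hi, s_to_ns(segment[1]))
    overlap_s = (t_hi - t_lo) / NS_PER_S
    if overlap_s < 2.0 * max_lag_s:
        raise InsufficientOverlapError(
            f"overlap {overlap_s:.2f} s shorter than 2 x max_lag {max_lag_s} s"
        )
    n = int(np.floor(overlap_s * fs_hz))
    grid = t_lo + np.round(np.arange(n) * (NS_PER_S / fs_hz)).astype(np.int64)
    a = np.interp(grid, r.timestamps, r.values)
    b = np.interp(grid, c.timestamps, c.values)
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.sqrt(np.sum(a**2)), np.sqrt(np.sum(b**2))
    if na == 0 or nb == 0:
        raise UndefinedCorrelationError("flat signal: correlation undefined")
    corr = signal.correlate(a, b, mode="full", method="fft") / (na * nb)
    lags = signal.correlation_lags(n, n, mode="full")
    # correlate(a, b)[lag l] = sum a[k+l] b[k]; cached ahead by +L seconds
    # means b(t) = truth(t - L) so the peak sits at l = -L*fs
    lag_s_grid = -lags / fs_hz
    m = np.abs(lag_s_grid) <= max_lag_s
    corr_m, lag_m = corr[m], lag_s_grid[m]
    k = int(np.argmax(corr_m))
    lag, peak = lag_m[k], corr_m[k]
    if 0 < k < len(corr_m) - 1:  # parabolic sub-sample refinement
        y0, y1, y2 = corr_m[k - 1], corr_m[k], corr_m[k + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            delta = 0.5 * (y0 - y2) / denom
            lag = lag + delta * (lag_m[k + 1] - lag_m[k])
            peak = y1 - 0.25 * (y0 - y2) * delta
    return LagEstimate(
        lag_s=float(np.clip(lag, -max_lag_s, max_lag_s)),
        peak_corr=float(peak),
        search_window_s=max_lag_s,
        segment_used=(int(t_lo), int(t_hi)),
    )


def fit_clock_map(
    lag: LagEstimate | None = None,
    pairs: list[tuple[int, int]] | None = None,
) -> ClockMap:
    """Clock map from a single lag estimate (drift 0) or anchor pairs.

    ``pairs`` are ``(device_ns, reference_ns)`` anchors; with two or more,
    offset and drift are fitted by least squares.
    """
    if pairs is not None and len(pairs) >= 2:
        dev = np.array([p[0] for p in pairs], dtype=float)
        ref = np.array([p[1] for p in pairs], dtype=float)
        slope, intercept = np.polyfit(dev, ref, 1)
        drift_ppm = (1.0 / slope - 1.0) * 1e6
        # reference = slope*(device - offset_ns)  =>  offset = -intercept/slope
        offset_s = -intercept / slope / NS_PER_S
        return ClockMap(offset_s=float(offset_s), drift_ppm=float(drift_ppm),
                        fit_pairs=tuple(pairs))
    if lag is not None:
        return ClockMap(offset_s=lag.lag_s, drift_ppm=0.0)
    raise ValueError("need a lag estimate or >= 2 anchor pairs")


@dataclass
class PatchResult:
    stream: TimestampedStream
    provenance: np.ndarray          # "streamed" | "cached" per sample
    gaps: list                      # (gap_start_ns, gap_end_ns) patched
    n_cached_used: int = 0


def patch_gaps(
    streamed: TimestampedStream,
    cached: TimestampedStream,
    clock_map: ClockMap,
    gap_threshold: float = 3.0,
) -> PatchResult:
    """Fill streamed transmission gaps with re-timestamped cached samples.

    A gap is an inter-sample interval exceeding ``gap_threshold`` times the
    nominal period.  Cached samples are mapped onto the reference clock and
    inserted strictly inside each gap; streamed samples are never modified,
    and exact timestamp collisions resolve in favor of the streamed copy.
    """
    if clock_map is None:
        raise ValueError("clock map required to re-timestamp cached data")
    mapped_ts = clock_map.apply_ns(cached.timestamps)
    order = np.argsort(mapped_ts)
    mapped_ts = mapped_ts[order]
    mapped_vals = cached.values[order]

    if len(streamed) == 0:
        out = TimestampedStream(
            streamed.device_id, streamed.metric, streamed.units,
            streamed.native_rate_hz, mapped_ts, mapped_vals,
        )
        return PatchResult(out, np.full(len(out), "cached", dtype=object),
                           gaps=[], n_cached_used=len(out))

    period_ns = NS_PER_S / streamed.native_rate_hz
    gap_ns = gap_threshold * period_ns
    gaps = []
    diffs = np.diff(streamed.timestamps)
    for i in np.nonzero(diffs > gap_ns)[0]:
        gaps.append((int(streamed.timestamps[i]), int(streamed.timestamps[i + 1])))

    ts = [streamed.timestamps]
    vals = [streamed.values]
    prov = [np.full(len(streamed), "streamed", dtype=object)]
    n_cached = 0
    half = np.int64(round(0.5 * period_ns))
    for g0, g1 in gaps:
        # keep half a nominal period clear of the gap edges so a sub-sample
        # clock-map error cannot duplicate the edge samples
        m = (mapped_ts >= g0 + half) & (mapped_ts <= g1 - half)
        m &= ~np.isin(mapped_ts, streamed.timestamps)
        if m.any():
            ts.append(mapped_ts[m])
            vals.append(mapped_vals[m])
            prov.append(np.full(m.sum(), "cached", dtype=object))
            n_cached += int(m.sum())
    all_ts = np.concatenate(ts)
    order = np.argsort(all_ts, kind="stable")
    out = TimestampedStream(
        streamed.device_id, streamed.metric, streamed.units,
        streamed.native_rate_hz, all_ts[order], np.concatenate(vals)[order],
    )
    return PatchResult(out, np.concatenate(prov)[order], gaps=gaps, n_cached_used=n_cached)
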