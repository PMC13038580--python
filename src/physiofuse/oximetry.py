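"""Tissue-oxygenation plausibility QC and placement-error statistics.

StO2 samples are rejected when physiologically implausible — below 5%,
above 95%, or jumping more than 20 percentage points from the last
ACCEPTED sample (so one spike cannot cascade into rejecting everything
after it).  Placement error compares each test location's synchronized,
filtered trace against the reference site as a per-tick percent
difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .streams import TimestampedStream


@dataclass(frozen=True)
class Sto2FilterConfig:
    low_pct: float = 5.0
    high_pct: float = 95.0
    jump_pct: float = 20.0

    def __post_init__(self):
        if not (0.0 <= self.low_pct < self.high_pct <= 100.0):
            raise ValueError("need 0 <= low < high <= 100")
        if self.jump_pct <= 0:
            raise ValueError("jump_pct must be > 0")


@dataclass
class RejectionReport:
    n_total: int
    n_rejected: int
    reason_counts: dict = field(default_factory=lambda: {"low": 0, "high": 0, "jump": 0})

    @property
    def rejection_rate_pct(self) -> float:
        return 100.0 * self.n_rejected / self.n_total if self.n_total else 0.0


def plausibility_filter(
    sto2: TimestampedStream, cfg: Sto2FilterConfig = Sto2FilterConfig()
) -> tuple[np.ndarray, RejectionReport]:
    """Causal plausibility mask over an StO2 trace (True = accepted).

    Rules, in precedence order (one primary reason per sample): value below
    ``low_pct``; value above ``high_pct``; absolute change from the last
    accepted sample above ``jump_pct``.  The first sample is exempt from
    the jump rule.
    """
    vals = sto2.values
    mask = np.zeros(len(vals), dtype=bool)
    counts = {"low": 0, "high": 0, "jump": 0}
    last_accepted = None
    for i, v in enumerate(vals):
        if v < cfg.low_pct:
            counts["low"] += 1
        elif v > cfg.high_pct:
            counts["high"] += 1
        elif last_accepted is not None and abs(v - last_accepted) > cfg.jump_pct:
            counts["jump"] += 1
        else:
            mask[i] = True
            last_accepted = v
    report = RejectionReport(
        n_total=len(vals),
        n_rejected=int((~mask).sum()) if len(vals) else 0,
        reason_counts=counts,
    )
    return mask, report


@dataclass
class PlacementErrorStats:
    n: int
    mean_signed_pct: float
    mean_abs_pct: float
    sd_pct: float
    n_excluded_zero_ref: int = 0


def placement_error_rate(
    test: TimestampedStream, reference: TimestampedStream
) -> PlacementErrorStats:
    """Percent difference of a test site vs the reference site.

    Both streams must already be filtered and share common tick timestamps
    (intersect on exact epoch-ns times).  Per-tick error is
    ``100 * (test - ref) / ref``; ticks where the reference is zero are
    excluded and counted.  Both the signed mean (bias direction) and the
    mean absolute error (magnitude) are reported.
    """
    common, ti, ri = np.intersect1d(
        test.timestamps, reference.timestamps, return_indices=True
    )
    if len(common) == 0:
        raise ValueError("no common ticks between test and reference streams")
    tv, rv = test.values[ti], reference.values[ri]
    nz = rv != 0
    err = 100.0 * (tv[nz] - rv[nz]) / rv[nz]
    return PlacementErrorStats(
        n=int(nz.sum()),
        mean_signed_pct=float(err.mean()) if nz.any() else np.nan,
        mean_abs_pct=float(np.abs(err).mean()) if nz.any() else np.nan,
        sd_pct=float(err.std(ddof=1)) if nz.sum() > 1 else np.nan,
        n_excluded_zero_ref=int((~nz).sum()),
    )


def location_summary(session_records: list[dict]) -> pd.DataFrame:
    """Grand per-location means across test cycles and subjects.

    ``session_records`` rows carry at least ``location`` plus any of
    ``rejection_rate_pct`` / ``mean_abs_error_pct`` /
    ``mean_signed_error_pct``; the summary reports each metric's mean and
    the available n per location.
    """
    df = pd.DataFrame(session_records)
    if "location" not in df.columns:
        raise ValueError("records need a 'location' field")
    metrics = [c for c in df.columns if c != "location"]
    agg = df.groupby("location")[metrics].agg(["mean", "count"])
    agg.columns = [f"{m}_{s}" for m, s in agg.columns]
    return agg.reset_index()
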