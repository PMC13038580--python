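"""Master-clock fusion with sample-and-hold placeholder semantics.

All device streams are projected onto a single fixed-rate tick grid (200 Hz
by default, matching the fastest integrated device).  Each cell of the
fused :class:`SessionTable` holds the latest valid sample of its stream at
or before the tick — repeated ("held") until a new sample arrives — so
every row is a complete, temporally aligned snapshot across devices.  A
per-cell freshness flag records whether the value is a fresh sample, a held
placeholder, or missing (tick precedes the stream's first sample).  No
interpolation is ever performed: every stored value is an actual device
sample, and :func:`deduplicate_held` inverts the placeholder expansion to
recover native-rate streams for analysis.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np

from .protocol import EventTimeline
from .streams import TimestampedStream

MISSING, HELD, FRESH = 0, 1, 2
_FLAG_NAMES = {MISSING: "missing", HELD: "held", FRESH: "fresh"}


@dataclass(frozen=True)
class SyncConfig:
    """Fusion parameters.

    ``t_start_ns``/``t_end_ns`` bound the tick grid (half-open interval);
    if None they default to the span of the input streams.  Ticks are
    spaced exactly ``round(1e9 / master_rate_hz)`` ns apart with no drift.
    """

    master_rate_hz: float = 200.0
    t_start_ns: int | None = None
    t_end_ns: int | None = None

    @property
    def tick_ns(self) -> int:
        return int(round(1e9 / self.master_rate_hz))


@dataclass
class StreamMeta:
    device_id: str
    metric: str
    units: str
    native_rate_hz: float


@dataclass
class SessionTable:
    """Fused session: one row per master tick, one column per device metric."""

    tick_times: np.ndarray                 # epoch-ns, int64
    columns: dict                          # key -> float array (NaN where missing)
    freshness: dict                        # key -> uint8 array of MISSING/HELD/FRESH
    meta: dict                             # key -> StreamMeta
    events: EventTimeline = field(default_factory=lambda: EventTimeline(()))

    def __post_init__(self):
        n = len(self.tick_times)
        for key in self.columns:
            if len(self.columns[key]) != n or len(self.freshness[key]) != n:
                raise ValueError(f"column {key} length mismatch with ticks")

    @property
    def n_rows(self) -> int:
        return len(self.tick_times)

    def rows_complete(self) -> bool:
        """Every cell carries a defined flag, and value is NaN iff missing."""
        for key, col in self.columns.items():
            fl = self.freshness[key]
            if not np.all(np.isnan(col) == (fl == MISSING)):
                return False
        return True


def synchronize(streams: list[TimestampedStream], cfg: SyncConfig = SyncConfig()) -> SessionTable:
    """Fuse streams onto the master tick grid by sample-and-hold.

    For each tick t and stream s, the cell is the latest VALID sample of s
    with timestamp <= t (a sample timestamped exactly at a tick belongs to
    that tick).  The cell is flagged fresh when that sample lies in
    ``(t - tick, t]``, held otherwise, and missing when no sample precedes
    the tick.  Invalid samples are treated as absent.
    """
    if not streams:
        raise ValueError("need at least one stream")
    for s in streams:
        s.validate()
        if s.native_rate_hz > cfg.master_rate_hz:
            warnings.warn(
                f"{s.key}: native rate {s.native_rate_hz} Hz above master "
                f"{cfg.master_rate_hz} Hz; fast samples will be dropped",
                stacklevel=2,
            )

    nonempty = [s for s in streams if s.only_valid().timestamps.size]
    t0 = cfg.t_start_ns
    t1 = cfg.t_end_ns
    if t0 is None:
        t0 = min(int(s.only_valid().timestamps[0]) for s in nonempty) if nonempty else 0
    tick = cfg.tick_ns
    if t1 is None:
        # default end: one tick past the last sample so every sample is
        # covered by at least one tick regardless of grid phase
        t1 = max(int(s.only_valid().timestamps[-1]) for s in nonempty) + tick if nonempty else 1
    n = max(int(np.ceil((t1 - t0) / tick)), 1)
    ticks = np.int64(t0) + tick * np.arange(n, dtype=np.int64)

    columns, freshness, meta = {}, {}, {}
    for s in streams:
        key = s.key
        sv = s.only_valid()
        col = np.full(n, np.nan)
        fl = np.full(n, MISSING, dtype=np.uint8)
        if sv.timestamps.size == 0:
            warnings.warn(f"{key}: no valid samples; column all-missing", stacklevel=2)
        else:
            idx = np.searchsorted(sv.timestamps, ticks, side="right") - 1
            have = idx >= 0
            col[have] = sv.values[idx[have]]
            samp_t = np.where(have, sv.timestamps[np.clip(idx, 0, None)], np.int64(0))
            fresh = have & (samp_t > ticks - tick)
            fl[have] = HELD
            fl[fresh] = FRESH
        columns[key] = col
        freshness[key] = fl
        meta[key] = StreamMeta(s.device_id, s.metric, s.units, s.native_rate_hz)
    return SessionTable(tick_times=ticks, columns=columns, freshness=freshness, meta=meta)


def deduplicate_held(table: SessionTable, key: str) -> TimestampedStream:
    """Inverse of placeholder expansion: fresh samples at their tick times.

    Recovers the native-rate stream up to tick quantization of the
    timestamps; held and missing cells are discarded.
    """
    if key not in table.columns:
        raise KeyError(f"no column {key!r}; have {sorted(table.columns)}")
    m = table.freshness[key] == FRESH
    meta = table.meta[key]
    return TimestampedStream(
        device_id=meta.device_id,
        metric=meta.metric,
        units=meta.units,
        native_rate_hz=meta.native_rate_hz,
        timestamps=table.tick_times[m],
        values=table.columns[key][m],
    )


# ----------------------------------------------------------------- HDF5 IO


def write_session(table: SessionTable, path) -> None:
    """Persist a fused session: shared /ticks, one group per device, one
    dataset per metric with a parallel freshness dataset, events as JSON."""
    with h5py.File(path, "w") as f:
        # track_times=False keeps files byte-identical across reruns
        f.create_dataset("ticks", data=table.tick_times, compression="gzip",
                         track_times=False)
        f.attrs["events_json"] = json.dumps(table.events.to_records())
        for key, col in table.columns.items():
            dev, metric = key.split("/", 1)
            g = f.require_group(dev)
            d = g.create_dataset(metric, data=col, compression="gzip",
                                 track_times=False)
            g.create_dataset(f"{metric}__freshness", data=table.freshness[key],
                             compression="gzip", track_times=False)
            m = table.meta[key]
            d.attrs["units"] = m.units
            d.attrs["native_rate_hz"] = m.native_rate_hz


def read_session(path) -> SessionTable:
    try:
        f = h5py.File(path, "r")
    except (OSError, FileNotFoundError) as exc:
        raise IOError(f"cannot open session file {path!r}: {exc}") from exc
    with f:
        ticks = f["ticks"][...]
        events = EventTimeline.from_records(json.loads(f.attrs.get("events_json", "[]")))
        columns, freshness, meta = {}, {}, {}
        for dev in f:
            if dev == "ticks":
                continue
            g = f[dev]
            for metric in g:
                if metric.endswith("__freshness"):
                    continue
                key = f"{dev}/{metric}"
                d = g[metric]
                columns[key] = d[...]
                freshness[key] = g[f"{metric}__freshness"][...]
                meta[key] = StreamMeta(dev, metric, str(d.attrs.get("units", "")),
                                       float(d.attrs.get("native_rate_hz", 0.0)))
    return SessionTable(tick_times=ticks, columns=columns, freshness=freshness,
                        meta=meta, events=events)
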