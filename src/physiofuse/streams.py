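"""Timestamped device streams and their plain-text serialization.

Every sensor metric handled by this package — ECG voltage, tissue
oxygenation, device-reported heart rate — is represented as a
:class:`TimestampedStream`: a single metric from a single device as parallel
arrays of epoch-nanosecond timestamps, values and validity flags, tagged
with a nominal native rate.  Nanosecond-integer timestamps are used
throughout so that multi-rate streams can be fused without floating-point
clock drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

NS_PER_S = 1_000_000_000


def s_to_ns(t_s: float | np.ndarray) -> np.ndarray | int:
    """Convert seconds to integer epoch-nanoseconds (round-to-nearest)."""
    out = np.round(np.asarray(t_s, dtype=float) * NS_PER_S).astype(np.int64)
    return int(out) if out.ndim == 0 else out


def ns_to_s(t_ns: np.ndarray | int) -> np.ndarray | float:
    out = np.asarray(t_ns, dtype=np.int64) / NS_PER_S
    return float(out) if out.ndim == 0 else out


@dataclass
class TimestampedStream:
    """One device metric sampled at its native rate.

    Parameters
    ----------
    device_id, metric, units
        Free-form labels (e.g. ``"polar"``, ``"hr"``, ``"bpm"``).
    native_rate_hz
        Nominal sampling rate.  Devices jitter around it; all processing
        uses the actual timestamps, never index arithmetic.
    timestamps
        Strictly increasing ``int64`` epoch-nanosecond array.
    values
        Float array, same length as ``timestamps``.
    valid
        Boolean array; invalid samples are skipped by fusion and analysis.
    """

    device_id: str
    metric: str
    units: str
    native_rate_hz: float
    timestamps: np.ndarray
    values: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if self.valid is None:
            self.valid = np.ones(len(self.timestamps), dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        self.validate()

    def validate(self) -> None:
        n = len(self.timestamps)
        if len(self.values) != n or len(self.valid) != n:
            raise ValueError(
                f"{self.key}: timestamps/values/valid lengths differ "
                f"({n}/{len(self.values)}/{len(self.valid)})"
            )
        if n > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError(f"{self.key}: timestamps not strictly increasing")
        if self.native_rate_hz <= 0:
            raise ValueError(f"{self.key}: native_rate_hz must be > 0")

    @property
    def key(self) -> str:
        """``device/metric`` identifier used in session files and CLIs."""
        return f"{self.device_id}/{self.metric}"

    @property
    def times_s(self) -> np.ndarray:
        return self.timestamps / NS_PER_S

    def __len__(self) -> int:
        return len(self.timestamps)

    def crop(self, t_start_ns: int, t_end_ns: int) -> "TimestampedStream":
        """Samples with ``t_start_ns <= t < t_end_ns``."""
        m = (self.timestamps >= t_start_ns) & (self.timestamps < t_end_ns)
        return replace(
            self, timestamps=self.timestamps[m], values=self.values[m], valid=self.valid[m]
        )

    def only_valid(self) -> "TimestampedStream":
        m = self.valid
        return replace(
            self, timestamps=self.timestamps[m], values=self.values[m], valid=self.valid[m]
        )

    def shift(self, offset_ns: int) -> "TimestampedStream":
        return replace(self, timestamps=self.timestamps + np.int64(offset_ns))

    # -- plain-text IO -------------------------------------------------

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            {"timestamp_ns": self.timestamps, "value": self.values, "valid": self.valid.astype(int)}
        )
        with open(path, "w") as fh:
            fh.write(
                f"# device_id={self.device_id} metric={self.metric} "
                f"units={self.units} native_rate_hz={self.native_rate_hz}\n"
            )
            df.to_csv(fh, index=False)

    @classmethod
    def from_csv(
        cls,
        path,
        device_id: str = "unknown",
        metric: str = "value",
        units: str = "",
        native_rate_hz: float = 1.0,
    ) -> "TimestampedStream":
        """Read ``timestamp_ns,value[,valid]`` CSV, honoring the header comment."""
        with open(path) as fh:
            first = fh.readline()
        meta = {}
        if first.startswith("#"):
            for tok in first[1:].split():
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    meta[k] = v
        df = pd.read_csv(path, comment="#")
        if "timestamp_ns" not in df.columns or "value" not in df.columns:
            raise ValueError(f"{path}: expected columns timestamp_ns,value[,valid]")
        valid = (
            df["valid"].to_numpy(dtype=bool)
            if "valid" in df.columns
            else np.ones(len(df), dtype=bool)
        )
        return cls(
            device_id=meta.get("device_id", device_id),
            metric=meta.get("metric", metric),
            units=meta.get("units", units),
            native_rate_hz=float(meta.get("native_rate_hz", native_rate_hz)),
            timestamps=df["timestamp_ns"].to_numpy(dtype=np.int64),
            values=df["value"].to_numpy(dtype=float),
            valid=valid,
        )
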