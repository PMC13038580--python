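"""Study protocol templates and event timelines.

A :class:`ProtocolTemplate` is an ordered list of labeled phases with
durations and phase parameters (target heart-rate zone as a fraction of
HRmax, or cuff pressure in mmHg).  :func:`make_timeline` lays a template out
on the epoch-nanosecond axis as a contiguous :class:`EventTimeline`, which
drives both the synthetic-session generator and phase-wise analysis
(segmentation, progress normalization, per-phase quality reports).

Built-in templates::

    occlusion : 180 s baseline, 60 s @ 100 mmHg, 60 s @ 150 mmHg,
                60 s @ 200 mmHg, 300 s recovery         (660 s total)
    exercise  : 120 s rest, 120 s mild (50-60 %HRmax),
                120 s moderate (60-70 %), 120 s high (70-80 %),
                240 s recovery                           (720 s total)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .streams import NS_PER_S, s_to_ns


class InvalidTemplateError(ValueError):
    pass


@dataclass(frozen=True)
class Phase:
    label: str
    duration_s: float
    #: e.g. {"hr_zone": (0.5, 0.6)} or {"pressure_mmhg": 100.0}
    params: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ProtocolTemplate:
    name: str
    phases: tuple[Phase, ...]

    def __post_init__(self):
        labels = [p.label for p in self.phases]
        if len(set(labels)) != len(labels):
            raise InvalidTemplateError(f"{self.name}: duplicate phase labels")
        for p in self.phases:
            if p.duration_s <= 0:
                raise InvalidTemplateError(
                    f"{self.name}/{p.label}: non-positive duration {p.duration_s}"
                )

    @property
    def total_duration_s(self) -> float:
        return float(sum(p.duration_s for p in self.phases))


@dataclass(frozen=True)
class Event:
    """A labeled interval (or instant, when end_ns == start_ns)."""

    label: str
    start_ns: int
    end_ns: int
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.label:
            raise ValueError("event label must be non-empty")
        if self.end_ns < self.start_ns:
            raise ValueError(f"{self.label}: end before start")

    @property
    def duration_s(self) -> float:
        return (self.end_ns - self.start_ns) / NS_PER_S


@dataclass(frozen=True)
class EventTimeline:
    events: tuple[Event, ...]

    @property
    def start_ns(self) -> int:
        return min(e.start_ns for e in self.events)

    @property
    def end_ns(self) -> int:
        return max(e.end_ns for e in self.events)

    def __iter__(self):
        return iter(self.events)

    def __len__(self):
        return len(self.events)

    def phase_of(self, t_ns: int) -> Event | None:
        """The interval containing t (half-open [start, end))."""
        for e in self.events:
            if e.start_ns <= t_ns < e.end_ns:
                return e
        return None

    def to_records(self) -> list[dict]:
        return [
            {"label": e.label, "start_ns": int(e.start_ns), "end_ns": int(e.end_ns),
             "params": dict(e.params)}
            for e in self.events
        ]

    @classmethod
    def from_records(cls, records) -> "EventTimeline":
        return cls(tuple(
            Event(r["label"], int(r["start_ns"]), int(r["end_ns"]), dict(r.get("params", {})))
            for r in records
        ))


def make_timeline(template: ProtocolTemplate, start_ns: int = 0) -> EventTimeline:
    """Lay a protocol out as contiguous non-overlapping labeled intervals.

    Phase boundaries are computed by cumulative sums in nanoseconds so that
    each phase ends exactly where the next begins and the total span equals
    the template duration.
    """
    events = []
    t = np.int64(start_ns)
    for p in template.phases:
        dur = s_to_ns(p.duration_s)
        events.append(Event(p.label, int(t), int(t + dur), dict(p.params)))
        t = t + dur
    return EventTimeline(tuple(events))


OCCLUSION_TEMPLATE = ProtocolTemplate(
    name="occlusion",
    phases=(
        Phase("baseline", 180.0, {"pressure_mmhg": 0.0}),
        Phase("occlusion_100", 60.0, {"pressure_mmhg": 100.0}),
        Phase("occlusion_150", 60.0, {"pressure_mmhg": 150.0}),
        Phase("occlusion_200", 60.0, {"pressure_mmhg": 200.0}),
        Phase("recovery", 300.0, {"pressure_mmhg": 0.0}),
    ),
)

EXERCISE_TEMPLATE = ProtocolTemplate(
    name="exercise",
    phases=(
        Phase("rest", 120.0, {"hr_zone": (0.0, 0.0)}),
        Phase("mild", 120.0, {"hr_zone": (0.50, 0.60)}),
        Phase("moderate", 120.0, {"hr_zone": (0.60, 0.70)}),
        Phase("high", 120.0, {"hr_zone": (0.70, 0.80)}),
        Phase("recovery", 240.0, {"hr_zone": (0.0, 0.0)}),
    ),
)

BUILTIN_TEMPLATES = {
    "occlusion": OCCLUSION_TEMPLATE,
    "exercise": EXERCISE_TEMPLATE,
}


def get_template(name: str) -> ProtocolTemplate:
    try:
        return BUILTIN_TEMPLATES[name]
    except KeyError:
        raise InvalidTemplateError(
            f"unknown protocol {name!r}; built-ins: {sorted(BUILTIN_TEMPLATES)}"
        ) from None
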