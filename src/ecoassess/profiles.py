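"""Behavioral profiles: per-participant activity/gait features and autonomy staging.

A profile aggregates, for each protocol activity unit, the frequency and
total duration of recognized events plus omission/repetition counts relative
to the expected number of repetitions, and combines them with the gait
parameters of the single and dual walking tasks.  The completed-activity
count is staged into autonomy classes with the cut-offs: >= 8 completed is a
good performance, 4-7 intermediate, below 4 poor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .events import EventInterval
from .gait import GaitParameters
from .scene import ACTIVITIES

__all__ = [
    "AUTONOMY_CLASSES",
    "DIAGNOSIS_CLASSES",
    "MAX_ACTIVITY_UNITS",
    "GOOD_CUTOFF",
    "INTERMEDIATE_CUTOFF",
    "ActivityUnit",
    "ProtocolSpec",
    "ActivityStats",
    "BehavioralProfile",
    "default_protocol",
    "build_profile",
    "stage_autonomy",
]

AUTONOMY_CLASSES = ("good", "intermediate", "poor")
DIAGNOSIS_CLASSES = ("HC", "MCI", "AD")

#: Total expected activity units in the default protocol (the maximum
#: completed-activity count).
MAX_ACTIVITY_UNITS = 13

#: Completed-activity cut-offs: >= GOOD_CUTOFF is good, >= INTERMEDIATE_CUTOFF
#: is intermediate, below that poor.
GOOD_CUTOFF = 8
INTERMEDIATE_CUTOFF = 4


@dataclass(frozen=True)
class ActivityUnit:
    """One protocol activity with its expected repetition count and the
    minimum recognized-event duration that counts one repetition as completed."""

    model_name: str
    expected_count: int
    min_completion_s: float = 10.0
    stem: str = ""

    def __post_init__(self) -> None:
        if self.expected_count < 1:
            raise ValueError(f"unit {self.model_name!r}: expected_count must be >= 1")
        if not self.stem:
            object.__setattr__(self, "stem", self.model_name)


@dataclass(frozen=True)
class ProtocolSpec:
    activity_units: tuple
    window_s: float = 900.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "activity_units", tuple(self.activity_units))
        names = [u.model_name for u in self.activity_units]
        if len(set(names)) != len(names):
            raise ValueError("duplicate activity units in protocol")

    @property
    def total_expected(self) -> int:
        return sum(u.expected_count for u in self.activity_units)

    def unit(self, model_name: str) -> ActivityUnit:
        for u in self.activity_units:
            if u.model_name == model_name:
                return u
        raise KeyError(model_name)


def default_protocol(window_s: float = 900.0) -> ProtocolSpec:
    units = tuple(
        ActivityUnit(a.model_name, a.expected_count, a.min_completion_s, a.stem)
        for a in ACTIVITIES
    )
    spec = ProtocolSpec(units, window_s)
    assert spec.total_expected == MAX_ACTIVITY_UNITS
    return spec


@dataclass(frozen=True)
class ActivityStats:
    frequency: int
    duration_s: float
    omissions: int
    repetitions: int
    completed_instances: int
    completed: bool


@dataclass
class BehavioralProfile:
    participant_id: str
    age: float
    activities: dict  # model_name -> ActivityStats
    activities_initiated: int
    activities_completed: int
    gait: dict  # "mono"/"dual" -> GaitParameters
    labels: dict = field(default_factory=dict)  # diagnosis / autonomy

    # -- serialization ---------------------------------------------------

    def to_feature_row(self, protocol: Optional[ProtocolSpec] = None) -> dict:
        protocol = protocol or default_protocol()
        row: dict = {"participant_id": self.participant_id, "age": float(self.age)}
        row.update(self.gait["mono"].to_feature_dict("single_task"))
        row.update(self.gait["dual"].to_feature_dict("dual_task"))
        for u in protocol.activity_units:
            st = self.activities[u.model_name]
            row[f"{u.stem}_frequency_of_event"] = float(st.frequency)
            row[f"{u.stem}_duration_of_event"] = float(st.duration_s)
            row[f"{u.stem}_omissions_of_event"] = float(st.omissions)
            row[f"{u.stem}_repetitions_of_event"] = float(st.repetitions)
            row[f"{u.stem}_completed_instances"] = float(st.completed_instances)
        row["activities_initiated"] = float(self.activities_initiated)
        row["activities_completed"] = float(self.activities_completed)
        for key, value in sorted(self.labels.items()):
            row[key] = value
        return row

    @classmethod
    def from_feature_row(cls, row: dict,
                         protocol: Optional[ProtocolSpec] = None) -> "BehavioralProfile":
        protocol = protocol or default_protocol()
        activities = {}
        for u in protocol.activity_units:
            freq = int(round(float(row[f"{u.stem}_frequency_of_event"])))
            comp = int(round(float(row[f"{u.stem}_completed_instances"])))
            activities[u.model_name] = ActivityStats(
                frequency=freq,
                duration_s=float(row[f"{u.stem}_duration_of_event"]),
                omissions=int(round(float(row[f"{u.stem}_omissions_of_event"]))),
                repetitions=int(round(float(row[f"{u.stem}_repetitions_of_event"]))),
                completed_instances=comp,
                completed=comp == u.expected_count,
            )
        labels = {k: row[k] for k in ("diagnosis", "autonomy", "autonomy_staged")
                  if k in row}
        return cls(
            participant_id=str(row["participant_id"]),
            age=float(row["age"]),
            activities=activities,
            activities_initiated=int(round(float(row["activities_initiated"]))),
            activities_completed=int(round(float(row["activities_completed"]))),
            gait={
                "mono": GaitParameters.from_feature_dict("single_task", row),
                "dual": GaitParameters.from_feature_dict("dual_task", row),
            },
            labels=labels,
        )


def _clip_to_window(iv: EventInterval, t0: float, t1: float) -> Optional[EventInterval]:
    s, e = max(iv.t_start, t0), min(iv.t_end, t1)
    if s >= e:
        return None
    return EventInterval(iv.model_name, s, e)


def build_profile(
    events: Iterable[EventInterval],
    gait: dict,
    protocol: ProtocolSpec,
    age: float,
    participant_id: str = "",
    labels: Optional[dict] = None,
    window_start: float = 0.0,
) -> BehavioralProfile:
    """Aggregate recognized events and gait parameters into a profile.

    Per unit: ``frequency`` is the number of recognized intervals of the
    unit's model inside the protocol window (straddling events are clipped),
    ``repetitions = max(0, frequency - expected)`` and
    ``omissions = max(0, expected - frequency)``.  A repetition counts as
    completed when its recognized interval lasts at least the unit's minimum
    completion duration; instance-level counts are capped at the expected
    count so that ``0 <= activities_completed <= activities_initiated <= 13``
    for the default protocol.  Events referencing models absent from the
    protocol are excluded with a warning.
    """
    t0, t1 = window_start, window_start + protocol.window_s
    known = {u.model_name for u in protocol.activity_units}
    per_model: dict = {name: [] for name in known}
    for iv in events:
        if iv.model_name not in known:
            warnings.warn(
                f"event model {iv.model_name!r} absent from protocol; excluded",
                stacklevel=2,
            )
            continue
        clipped = _clip_to_window(iv, t0, t1)
        if clipped is not None:
            per_model[iv.model_name].append(clipped)

    activities: dict = {}
    initiated = 0
    completed = 0
    for u in protocol.activity_units:
        ivs = per_model[u.model_name]
        freq = len(ivs)
        duration = sum(iv.duration for iv in ivs)
        qualifying = sum(1 for iv in ivs if iv.duration >= u.min_completion_s - 1e-9)
        comp_inst = min(qualifying, u.expected_count)
        init_inst = min(freq, u.expected_count)
        activities[u.model_name] = ActivityStats(
            frequency=freq,
            duration_s=duration,
            omissions=max(0, u.expected_count - freq),
            repetitions=max(0, freq - u.expected_count),
            completed_instances=comp_inst,
            completed=comp_inst == u.expected_count,
        )
        initiated += init_inst
        completed += comp_inst

    if set(gait) != {"mono", "dual"}:
        raise ValueError("gait must map exactly the keys 'mono' and 'dual'")

    return BehavioralProfile(
        participant_id=participant_id,
        age=age,
        activities=activities,
        activities_initiated=initiated,
        activities_completed=completed,
        gait=dict(gait),
        labels=dict(labels or {}),
    )


def stage_autonomy(activities_completed: int) -> str:
    """Stage a completed-activity count into good / intermediate / poor."""
    n = int(activities_completed)
    if n != activities_completed:
        raise ValueError("activities_completed must be an integer count")
    if not 0 <= n <= MAX_ACTIVITY_UNITS:
        raise ValueError(f"activities_completed must be in [0, {MAX_ACTIVITY_UNITS}]")
    if n >= GOOD_CUTOFF:
        return "good"
    if n >= INTERMEDIATE_CUTOFF:
        return "intermediate"
    return "poor"
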