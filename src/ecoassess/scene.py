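"""Default scene geometry, activity-model library and assessment protocol.

The observation room is a 6 m x 5 m rectangle with one contextual zone per
activity of the assessment protocol plus a 4 m walking corridor.  Each
activity model follows the same formalism: the person occupies the activity's
zone, displays the activity's characteristic posture, and the zone occupancy
must have lasted at least :data:`ZONE_MIN_DURATION_S` seconds before the
event starts to be recognized.

The walking tasks (single task and dual task, i.e. walking while counting
backwards) share one ``walking_task`` model over the corridor zone; they are
told apart by protocol order (the single task is performed first), see
:func:`assign_walk_tasks`.
"""

from __future__ import annotations

from dataclasses import dataclass

from .events import Constraint, EventInterval, EventModel, Zone

__all__ = [
    "ROOM_SIZE",
    "HOME_POSITION",
    "ZONE_MIN_DURATION_S",
    "WALK_MODEL",
    "ActivitySpec",
    "ACTIVITIES",
    "default_zones",
    "default_event_models",
    "zone_center",
    "staging_point",
    "corridor_endpoints",
    "assign_walk_tasks",
]

ROOM_SIZE = (6.0, 5.0)
HOME_POSITION = (0.6, 0.6)

#: Half side length of a square activity zone.
ZONE_HALF = 0.4

#: Zone occupancy required before a composite event starts being recognized.
ZONE_MIN_DURATION_S = 2.0

WALK_MODEL = "walking_task"
WALK_TASK_NAMES = ("mono_task", "dual_task")

# zone centers (meters); the corridor is a 4 m x 0.8 m band across the room
_ZONE_CENTERS = {
    "Plant": (0.8, 4.4),
    "Drink": (2.2, 4.4),
    "PharmacyBasket": (3.6, 4.4),
    "FinanceDesk": (5.2, 4.4),
    "TV": (5.4, 2.5),
    "Phone": (5.0, 0.6),
    "ChairReadingTable": (3.6, 0.6),
    "BusMap": (2.2, 0.6),
}
_CORRIDOR = (0.5, 2.1, 4.5, 2.9)  # x0, y0, x1, y1

# staging points sit 0.4 m outside each zone; the person idles there between
# activities so zone occupancy starts/ends exactly at scheduled times
_STAGING = {
    "Plant": (0.8, 3.6),
    "Drink": (2.2, 3.6),
    "PharmacyBasket": (3.6, 3.6),
    "FinanceDesk": (5.2, 3.6),
    "TV": (5.4, 1.7),
    "Phone": (5.0, 1.4),
    "ChairReadingTable": (3.6, 1.4),
    "BusMap": (2.2, 1.4),
}
CORRIDOR_STAGING_IN = (0.7, 1.7)
CORRIDOR_STAGING_OUT = (4.3, 3.3)


@dataclass(frozen=True)
class ActivitySpec:
    """One protocol activity: its zone, posture, expected repetitions and the
    minimum recognized duration that counts the activity as completed."""

    model_name: str
    zone: str
    posture: str
    expected_count: int
    min_completion_s: float
    stem: str  # feature-name stem used in behavioral-profile columns


#: The 13 expected activity units of the 15-minute assessment protocol
#: (sum of expected counts = 13, the protocol's maximum completed count).
ACTIVITIES = (
    ActivitySpec("watering_plant", "Plant", "bending", 1, 10.0, "person_watering_plant"),
    ActivitySpec("preparing_drink", "Drink", "bending", 2, 10.0, "person_preparing_drink"),
    ActivitySpec("medication_preparation", "PharmacyBasket", "bending", 2, 10.0,
                 "person_using_pharmacybasket"),
    ActivitySpec("managing_finance", "FinanceDesk", "sitting", 2, 10.0,
                 "person_managing_finance"),
    ActivitySpec("watching_tv", "TV", "sitting", 1, 10.0, "person_watching_tv"),
    ActivitySpec("using_phone", "Phone", "sitting", 2, 5.0, "person_talking_on_phone"),
    ActivitySpec("reading_article", "ChairReadingTable", "sitting", 2, 10.0,
                 "person_reading_inchairreadingtable"),
    ActivitySpec("searching_bus_line", "BusMap", "bending", 1, 10.0,
                 "person_searching_busline"),
)

ACTIVITY_BY_NAME = {a.model_name: a for a in ACTIVITIES}


def default_zones() -> list:
    zones = [
        Zone.rectangle(name, cx - ZONE_HALF, cy - ZONE_HALF, cx + ZONE_HALF, cy + ZONE_HALF)
        for name, (cx, cy) in _ZONE_CENTERS.items()
    ]
    zones.append(Zone.rectangle("WalkCorridor", *_CORRIDOR))
    return zones


def zone_center(name: str) -> tuple:
    if name == "WalkCorridor":
        x0, y0, x1, y1 = _CORRIDOR
        return ((x0 + x1) / 2, (y0 + y1) / 2)
    return _ZONE_CENTERS[name]


def staging_point(zone: str) -> tuple:
    return _STAGING[zone]


def corridor_endpoints() -> tuple:
    """(entry, exit) centroid positions of the scripted corridor walk."""
    x0, y0, x1, y1 = _CORRIDOR
    yc = (y0 + y1) / 2
    return (x0 + 0.2, yc), (x1 - 0.2, yc)


def _zone_posture_model(name: str, zone: str, posture: str) -> EventModel:
    return EventModel(
        name=name,
        components={"c1": f"Person_in_zone_{zone}", "c2": f"Person_{posture}"},
        constraints=(
            Constraint("overlap", {"components": ["c1", "c2"]}),
            Constraint("min_duration_before", {"component": "c1",
                                               "seconds": ZONE_MIN_DURATION_S}),
        ),
    )


def default_event_models() -> list:
    models = [_zone_posture_model(a.model_name, a.zone, a.posture) for a in ACTIVITIES]
    models.append(_zone_posture_model(WALK_MODEL, "WalkCorridor", "standing"))
    return models


def assign_walk_tasks(events) -> list:
    """Label ``walking_task`` intervals as mono/dual by protocol order.

    The protocol performs the single walking task first and the dual task
    second; the recognizer cannot distinguish them from the track alone, so
    the first recognized corridor walk becomes ``mono_task`` and the second
    ``dual_task``.  Further corridor walks are dropped.
    """
    walks = sorted((e for e in events if e.model_name == WALK_MODEL),
                   key=lambda e: e.t_start)
    out = []
    for name, iv in zip(WALK_TASK_NAMES, walks):
        out.append(EventInterval(name, iv.t_start, iv.t_end))
    return out
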