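"""Synthetic cohort simulator: schedules, track-stream rendering, profiles.

Stands in for the (unavailable) clinic video recordings.  Per-class activity
schedules are calibrated to the published cohort statistics: completed
activities per autonomy class (good 10.04 +/- 1.4, intermediate 5.5 +/- 1.2,
poor 1.54 +/- 1.4), walking-task times and ages per diagnosis group, and the
49-participant class composition (22/16/11 autonomy, 14/23/12 diagnosis).

Rendering is aligned to the frame grid so the recognizer output on a
noiseless stream matches the schedule's ground-truth event intervals exactly:
the person idles at a staging point outside each zone, hops to the zone
center 2.5 s before adopting the activity posture (satisfying the 2 s
zone-occupancy constraint), and hops out 0.5 s after releasing it.  Transits
move at 1 m/s along Manhattan legs so that incidental zone/corridor crossings
stay below the recognizer's minimum-duration constraint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .events import EventInterval, TrackStream
from .profiles import AUTONOMY_CLASSES, DIAGNOSIS_CLASSES, MAX_ACTIVITY_UNITS
from . import scene as sc

__all__ = [
    "AUTONOMY_COMPLETED_CALIBRATION",
    "AGE_CALIBRATION",
    "SINGLE_TASK_TIME_CALIBRATION",
    "DUAL_TASK_TIME_CALIBRATION",
    "TABLE_COMPOSITION",
    "DEFAULT_DIAGNOSIS_CALIBRATION",
    "NoiseConfig",
    "CohortConfig",
    "ScheduledActivity",
    "WalkTask",
    "GroundTruthSchedule",
    "ParticipantRecord",
    "draw_completed_count",
    "generate_schedule",
    "render_track_stream",
    "simulate_participant",
    "simulate_cohort",
    "draw_feature_profile",
]

# -- published calibration targets ------------------------------------------

#: Completed-activity count per autonomy class: (mean, sd).
AUTONOMY_COMPLETED_CALIBRATION = {
    "good": (10.04, 1.4),
    "intermediate": (5.5, 1.2),
    "poor": (1.54, 1.4),
}

#: Age (years) per diagnosis group: (mean, sd).
AGE_CALIBRATION = {"HC": (74.1, 6.6), "MCI": (77.6, 6.2), "AD": (82.0, 8.0)}

#: Single walking-task time (s) per diagnosis group.
SINGLE_TASK_TIME_CALIBRATION = {
    "HC": (10.79, 1.31),
    "MCI": (11.43, 2.97),
    "AD": (14.36, 3.83),
}

#: Dual walking-task time (s) per diagnosis group.
DUAL_TASK_TIME_CALIBRATION = {
    "HC": (14.79, 4.26),
    "MCI": (18.35, 8.78),
    "AD": (23.25, 8.65),
}

#: Initiated-minus-completed activity gap per diagnosis group (cohort means).
INITIATED_GAP_CALIBRATION = {"HC": (1.64, 0.8), "MCI": (2.82, 0.8), "AD": (2.91, 0.8)}

#: Joint (autonomy, diagnosis) composition of the 49-participant cohort.
TABLE_COMPOSITION = {
    ("good", "HC"): 13,
    ("good", "MCI"): 9,
    ("intermediate", "HC"): 1,
    ("intermediate", "MCI"): 10,
    ("intermediate", "AD"): 5,
    ("poor", "MCI"): 4,
    ("poor", "AD"): 7,
}

#: Profile-level simulation defaults per diagnosis group where published.
DEFAULT_DIAGNOSIS_CALIBRATION = {
    "HC": {
        "age": AGE_CALIBRATION["HC"],
        "single_task_total_duration": SINGLE_TASK_TIME_CALIBRATION["HC"],
        "dual_task_total_duration": DUAL_TASK_TIME_CALIBRATION["HC"],
        "activities_initiated": (11.64, 1.15),
        "activities_completed": (10.00, 1.47),
    },
    "MCI": {
        "age": AGE_CALIBRATION["MCI"],
        "single_task_total_duration": SINGLE_TASK_TIME_CALIBRATION["MCI"],
        "dual_task_total_duration": DUAL_TASK_TIME_CALIBRATION["MCI"],
        "activities_initiated": (9.39, 2.46),
        "activities_completed": (6.57, 3.27),
    },
    "AD": {
        "age": AGE_CALIBRATION["AD"],
        "single_task_total_duration": SINGLE_TASK_TIME_CALIBRATION["AD"],
        "dual_task_total_duration": DUAL_TASK_TIME_CALIBRATION["AD"],
        "activities_initiated": (5.83, 3.61),
        "activities_completed": (2.92, 2.27),
    },
}

# rendering constants
TRANSIT_SPEED_MPS = 1.0
PRE_POSTURE_S = 2.5   # standing inside the zone before the activity posture
POST_POSTURE_S = 0.5  # standing inside the zone after the activity posture
FEET_BASE_M = 0.06    # inter-feet distance between steps while walking
FEET_PEAK_M = 0.36    # inter-feet distance at a step peak
FEET_IDLE_HALF_M = 0.05


@dataclass(frozen=True)
class NoiseConfig:
    dropout_prob: float = 0.0
    position_jitter_sd_m: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_prob < 1.0:
            raise ValueError("dropout_prob must be in [0, 1)")
        if self.position_jitter_sd_m < 0:
            raise ValueError("position_jitter_sd_m must be >= 0")


@dataclass(frozen=True)
class CohortConfig:
    composition: tuple = tuple(sorted(TABLE_COMPOSITION.items()))
    frame_rate: float = 10.0
    noise: NoiseConfig = NoiseConfig()
    seed: int = 0

    def __post_init__(self) -> None:
        comp = dict(self.composition)
        for (aut, diag), n in comp.items():
            if aut not in AUTONOMY_CLASSES or diag not in DIAGNOSIS_CLASSES:
                raise ValueError(f"unknown class pair ({aut!r}, {diag!r})")
            if n <= 0:
                raise ValueError("composition counts must be positive")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_participants(self) -> int:
        return sum(n for _, n in self.composition)

    def roster(self) -> list:
        """Deterministic participant roster: (id, autonomy, diagnosis)."""
        comp = dict(self.composition)
        out = []
        i = 1
        for aut in AUTONOMY_CLASSES:
            for diag in DIAGNOSIS_CLASSES:
                for _ in range(comp.get((aut, diag), 0)):
                    out.append((f"p{i:03d}", aut, diag))
                    i += 1
        return out


@dataclass(frozen=True)
class ScheduledActivity:
    model_name: str
    zone: str
    posture: str
    t_arrive: float  # hop into the zone (start of occupancy)
    t_start: float   # activity posture adopted; ground-truth event start
    t_end: float     # posture released; ground-truth event end
    t_leave: float   # hop out of the zone (end of occupancy)
    completed: bool


@dataclass(frozen=True)
class WalkTask:
    kind: str        # "mono" | "dual"
    t_entry: float   # corridor occupancy start
    t_exit: float    # corridor occupancy end
    start_pos: tuple
    end_pos: tuple
    step_times: tuple
    n_steps: int

    @property
    def duration(self) -> float:
        return self.t_exit - self.t_entry


@dataclass
class GroundTruthSchedule:
    participant_id: str
    autonomy: str
    diagnosis: str
    age: float
    walk_mono: WalkTask
    walk_dual: WalkTask
    activities: list
    iadl_window: tuple  # (t0, t1)
    scheduled_initiated: int
    scheduled_completed: int
    waypoints: list      # (t, x, y) piecewise-linear centroid path
    posture_spans: list  # (t0, t1, posture); default posture is standing

    def ground_truth_events(self) -> list:
        """Event intervals the recognizer produces on a noiseless rendering."""
        out = [
            EventInterval("mono_task",
                          self.walk_mono.t_entry + sc.ZONE_MIN_DURATION_S,
                          self.walk_mono.t_exit),
            EventInterval("dual_task",
                          self.walk_dual.t_entry + sc.ZONE_MIN_DURATION_S,
                          self.walk_dual.t_exit),
        ]
        out.extend(
            EventInterval(a.model_name, a.t_start, a.t_end) for a in self.activities
        )
        return out

    @property
    def end_time(self) -> float:
        return self.waypoints[-1][0]


def draw_completed_count(autonomy_class: str, rng: np.random.Generator,
                         discretize: bool = True):
    """Draw a completed-activity count from the class-calibrated Gaussian.

    With ``discretize`` the draw is rounded to the nearest integer and clipped
    to ``[0, 13]`` (draw -> round -> clip); otherwise the raw Gaussian value
    is returned, which preserves the calibrated mean exactly.
    """
    mean, sd = AUTONOMY_COMPLETED_CALIBRATION[autonomy_class]
    v = rng.normal(mean, sd)
    if not discretize:
        return float(v)
    return int(np.clip(round(v), 0, MAX_ACTIVITY_UNITS))


def _draw_walk_duration(diagnosis: str, rng: np.random.Generator,
                        minimum: float = 5.0) -> tuple:
    """Single/dual walking-task durations; the dual task is never faster."""
    single = max(minimum, rng.normal(*SINGLE_TASK_TIME_CALIBRATION[diagnosis]))
    for _ in range(100):
        dual = rng.normal(*DUAL_TASK_TIME_CALIBRATION[diagnosis])
        if dual >= single:
            return single, dual
    return single, single + abs(rng.normal(2.0, 1.0))


def _manhattan(p0: tuple, p1: tuple) -> list:
    """Axis-aligned legs p0 -> (p0.x, p1.y) -> p1 (degenerate legs dropped)."""
    legs = []
    if p0[1] != p1[1]:
        legs.append((p0[0], p1[1]))
    if p0[0] != p1[0]:
        legs.append(p1)
    return legs or [p1]


class _Timeline:
    """Waypoint builder; all times snapped to the frame grid."""

    def __init__(self, frame_rate: float, start_pos: tuple, start_t: float = 0.0):
        self.fr = frame_rate
        self.dt = 1.0 / frame_rate
        self.waypoints = [(self.snap(start_t), float(start_pos[0]), float(start_pos[1]))]
        self.postures: list = []

    def snap(self, t: float) -> float:
        return round(t * self.fr) / self.fr

    @property
    def t(self) -> float:
        return self.waypoints[-1][0]

    @property
    def pos(self) -> tuple:
        return self.waypoints[-1][1], self.waypoints[-1][2]

    def _add(self, t: float, pos: tuple) -> None:
        t = self.snap(t)
        if t < self.t - 1e-9:
            raise ValueError("timeline must be non-decreasing")
        if t > self.t:
            self.waypoints.append((t, float(pos[0]), float(pos[1])))

    def wait_until(self, t: float) -> None:
        self._add(t, self.pos)

    def transit(self, target: tuple, speed: float = TRANSIT_SPEED_MPS) -> None:
        """Move along Manhattan legs at constant speed."""
        for leg in _manhattan(self.pos, target):
            d = float(np.hypot(leg[0] - self.pos[0], leg[1] - self.pos[1]))
            if d > 0:
                self._add(self.snap(self.t + max(d / speed, self.dt)), leg)

    def hop(self, target: tuple) -> None:
        """Jump to ``target`` over a single frame (exact occupancy boundaries)."""
        self._add(self.t + self.dt, target)

    def glide(self, target: tuple, duration: float) -> None:
        """Linear motion to ``target`` over ``duration`` seconds."""
        self._add(self.t + duration, target)

    def posture_span(self, t0: float, t1: float, posture: str) -> None:
        self.postures.append((self.snap(t0), self.snap(t1), posture))


def generate_schedule(
    participant_id: str,
    autonomy: str,
    diagnosis: str,
    rng: np.random.Generator,
    frame_rate: float = 10.0,
) -> GroundTruthSchedule:
    """Generate one participant's ground-truth schedule.

    The protocol order is: single walking task, dual walking task, then the
    IADL window.  The completed-activity count is drawn from the autonomy
    class calibration (draw -> round -> clip) and the initiated count adds a
    diagnosis-calibrated gap.  Which activity instances are completed,
    initiated-but-not-completed or omitted is a uniform draw over the 13
    expected instances.
    """
    tl = _Timeline(frame_rate, sc.HOME_POSITION)
    snap = tl.snap

    completed = draw_completed_count(autonomy, rng)
    gap_mean, gap_sd = INITIATED_GAP_CALIBRATION[diagnosis]
    gap = int(np.clip(round(rng.normal(gap_mean, gap_sd)), 0, MAX_ACTIVITY_UNITS))
    initiated = min(MAX_ACTIVITY_UNITS, completed + gap)
    age = float(np.clip(rng.normal(*AGE_CALIBRATION[diagnosis]), 60.0, 100.0))
    d_single, d_dual = _draw_walk_duration(diagnosis, rng)
    d_single, d_dual = snap(d_single), snap(d_dual)

    # --- scenario 1: walking tasks ---------------------------------------
    entry, exit_ = sc.corridor_endpoints()
    tl.wait_until(2.0)

    def scripted_walk(kind: str, start: tuple, end: tuple, duration: float) -> WalkTask:
        t_entry = snap(tl.t + tl.dt)
        tl.hop(start)
        tl.glide(end, duration - tl.dt)
        step_len = float(np.clip(rng.normal(0.45, 0.04), 0.35, 0.60))
        path_len = float(np.hypot(end[0] - start[0], end[1] - start[1]))
        n_steps = max(4, int(round(path_len / step_len)))
        steps = tuple(snap(t_entry + (i + 0.5) * duration / n_steps)
                      for i in range(n_steps))
        return WalkTask(kind, t_entry, snap(t_entry + duration), start, end,
                        steps, n_steps)

    tl.transit(sc.CORRIDOR_STAGING_IN)
    tl.wait_until(tl.t + 1.0)
    mono = scripted_walk("mono", entry, exit_, d_single)
    tl.hop(sc.CORRIDOR_STAGING_OUT)
    tl.wait_until(tl.t + 2.0)
    dual = scripted_walk("dual", exit_, entry, d_dual)
    tl.hop(sc.CORRIDOR_STAGING_IN)

    # --- scenario 2: IADL window ------------------------------------------
    iadl_start = snap(tl.t + 1.0)
    tl.wait_until(iadl_start)

    instances = [a for a in sc.ACTIVITIES for _ in range(a.expected_count)]
    order = rng.permutation(len(instances))
    roles = ["completed"] * completed + ["initiated"] * (initiated - completed)
    roles += ["omitted"] * (len(instances) - len(roles))
    # role k is assigned to the instance at position order[k]; visit order is
    # a second independent shuffle so completion status and timing decouple
    performed = [(instances[i], roles[k]) for k, i in enumerate(order)
                 if roles[k] != "omitted"]
    visit_order = rng.permutation(len(performed))
    performed = [performed[i] for i in visit_order]

    activities = []
    for spec, role in performed:
        done = role == "completed"
        if done:
            lo, hi = (10.0, 20.0) if spec.min_completion_s <= 5.0 else (16.0, 40.0)
        else:
            lo, hi = 2.5, 4.4
        duration = snap(rng.uniform(lo, hi))
        center = sc.zone_center(spec.zone)
        staging = sc.staging_point(spec.zone)
        tl.transit(staging)
        tl.wait_until(tl.t + rng.uniform(1.0, 3.0))
        t_arrive = snap(tl.t + tl.dt)
        tl.hop(center)
        t_start = snap(t_arrive + PRE_POSTURE_S)
        t_end = snap(t_start + duration)
        t_leave = snap(t_end + POST_POSTURE_S)
        tl.wait_until(t_leave - tl.dt)
        tl.hop(staging)
        tl.posture_span(t_start, t_end, spec.posture)
        activities.append(ScheduledActivity(
            spec.model_name, spec.zone, spec.posture,
            t_arrive, t_start, t_end, t_leave, done,
        ))

    tl.wait_until(tl.t + 2.0)
    window = (iadl_start, snap(iadl_start + 900.0))
    if activities and activities[-1].t_leave > window[1]:
        raise ValueError("schedule does not fit the 15-minute window")

    return GroundTruthSchedule(
        participant_id=participant_id,
        autonomy=autonomy,
        diagnosis=diagnosis,
        age=age,
        walk_mono=mono,
        walk_dual=dual,
        activities=activities,
        iadl_window=window,
        scheduled_initiated=initiated,
        scheduled_completed=completed,
        waypoints=tl.waypoints,
        posture_spans=tl.postures,
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _feet_distance_signal(t: np.ndarray, walk: WalkTask) -> np.ndarray:
    """Triangular inter-feet distance bumps peaking at the scripted steps."""
    d = np.full(len(t), FEET_BASE_M)
    if not walk.step_times:
        return d
    gaps = np.diff(walk.step_times)
    w = 0.4 * (float(gaps.min()) if len(gaps) else walk.duration / 2)
    w = max(w, 0.2)
    for s in walk.step_times:
        tri = 1.0 - np.abs(t - s) / w
        bump = FEET_BASE_M + (FEET_PEAK_M - FEET_BASE_M) * np.clip(tri, 0.0, 1.0)
        d = np.maximum(d, bump)
    return d


def render_track_stream(
    schedule: GroundTruthSchedule,
    noise: NoiseConfig = NoiseConfig(),
    rng: Optional[np.random.Generator] = None,
    frame_rate: float = 10.0,
) -> tuple:
    """Render a schedule into a track stream; returns (stream, ground_truth).

    The centroid follows the schedule's piecewise-linear waypoints; postures
    follow the scheduled spans (standing by default).  Feet oscillate along
    the walking direction during walking tasks and keep a small static offset
    otherwise.  Per-frame dropout and Gaussian position jitter are applied
    from the noise configuration.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    wp = np.asarray(schedule.waypoints, dtype=float)
    t_final = wp[-1, 0]
    n = int(round(t_final * frame_rate)) + 1
    t = np.arange(n) / frame_rate
    x = np.interp(t, wp[:, 0], wp[:, 1])
    y = np.interp(t, wp[:, 0], wp[:, 2])

    posture = np.array(["standing"] * n, dtype=object)
    for t0, t1, label in schedule.posture_spans:
        i = int(round(t0 * frame_rate))
        j = int(round(t1 * frame_rate))
        posture[i:j] = label

    # feet: static offset outside walks, scripted oscillation inside
    lfx = x - FEET_IDLE_HALF_M
    lfy = y.copy()
    rfx = x + FEET_IDLE_HALF_M
    rfy = y.copy()
    for walk in (schedule.walk_mono, schedule.walk_dual):
        i = int(round(walk.t_entry * frame_rate))
        j = int(round(walk.t_exit * frame_rate))
        seg_t = t[i:j]
        d = _feet_distance_signal(seg_t, walk)
        direction = np.array(walk.end_pos) - np.array(walk.start_pos)
        direction = direction / np.linalg.norm(direction)
        lfx[i:j] = x[i:j] - 0.5 * d * direction[0]
        lfy[i:j] = y[i:j] - 0.5 * d * direction[1]
        rfx[i:j] = x[i:j] + 0.5 * d * direction[0]
        rfy[i:j] = y[i:j] + 0.5 * d * direction[1]

    if noise.position_jitter_sd_m > 0:
        sd = noise.position_jitter_sd_m
        x = x + rng.normal(0, sd, n)
        y = y + rng.normal(0, sd, n)
        lfx = lfx + rng.normal(0, sd, n)
        lfy = lfy + rng.normal(0, sd, n)
        rfx = rfx + rng.normal(0, sd, n)
        rfy = rfy + rng.normal(0, sd, n)

    present = np.ones(n, dtype=bool)
    if noise.dropout_prob > 0:
        present = rng.random(n) >= noise.dropout_prob

    for arr in (x, y, lfx, lfy, rfx, rfy):
        arr[~present] = np.nan
    posture[~present] = None

    stream = TrackStream(t, present, x, y, posture, lfx, lfy, rfx, rfy, frame_rate)
    return stream, schedule.ground_truth_events()


@dataclass
class ParticipantRecord:
    schedule: GroundTruthSchedule
    stream: TrackStream
    gt_events: list


def simulate_participant(
    participant_id: str,
    autonomy: str,
    diagnosis: str,
    seed_seq: np.random.SeedSequence,
    frame_rate: float = 10.0,
    noise: NoiseConfig = NoiseConfig(),
) -> ParticipantRecord:
    rng = np.random.default_rng(seed_seq)
    schedule = generate_schedule(participant_id, autonomy, diagnosis, rng, frame_rate)
    stream, gt = render_track_stream(schedule, noise, rng, frame_rate)
    return ParticipantRecord(schedule, stream, gt)


def simulate_cohort(config: CohortConfig) -> list:
    """Simulate the full cohort; bit-reproducible given (config, seed)."""
    roster = config.roster()
    children = np.random.SeedSequence(config.seed).spawn(len(roster))
    return [
        simulate_participant(pid, aut, diag, child,
                             config.frame_rate, config.noise)
        for (pid, aut, diag), child in zip(roster, children)
    ]


def draw_feature_profile(class_label: str, calibration: dict,
                         rng: np.random.Generator) -> dict:
    """Draw one profile-level feature vector from class-conditional Gaussians.

    ``calibration`` maps class -> {feature: (mean, sd)}; features are drawn
    independently (no covariance structure is published).
    """
    if class_label not in calibration:
        raise KeyError(f"no calibration for class {class_label!r}")
    spec = calibration[class_label]
    return {name: float(rng.normal(mean, sd)) for name, (mean, sd) in spec.items()}
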