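"""Constraint-based recognition of primitive states and composite activity events.

The recognizer consumes a tracked-person stream (per-frame position, posture
and foot coordinates) together with a scene description given as named
floor-plane polygons ("contextual zones").  Primitive states are per-frame
predicates (zone occupancy, posture); composite events are declarative models
combining primitive states or other models under temporal constraints.

Time semantics: all intervals are half-open ``[t_start, t_end)`` in seconds
and constraints are evaluated on the discrete frame grid, which makes a
brute-force instant-wise oracle exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import shapely
from shapely.geometry import Polygon

__all__ = [
    "POSTURES",
    "DEFAULT_GAP_MERGE_S",
    "TrackFrame",
    "TrackStream",
    "Zone",
    "PrimitiveStateInterval",
    "Constraint",
    "EventModel",
    "EventInterval",
    "detect_primitive_states",
    "recognize_composite_events",
    "evaluate_detection",
    "evaluate_detection_pooled",
]

POSTURES = ("standing", "sitting", "bending")

#: Two same-state runs separated by less than this many seconds (e.g. a short
#: tracking dropout) are merged into one primitive-state interval.
DEFAULT_GAP_MERGE_S = 0.5

#: Maximum depth of nested composite-model references.
MAX_MODEL_DEPTH = 4


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrackFrame:
    """One frame of a tracked-person stream.

    When ``person_present`` is false all spatial fields and the posture are
    absent (``None``).
    """

    t: float
    person_present: bool = True
    x: Optional[float] = None
    y: Optional[float] = None
    posture: Optional[str] = None
    lfx: Optional[float] = None
    lfy: Optional[float] = None
    rfx: Optional[float] = None
    rfy: Optional[float] = None


class TrackStream:
    """Time-ordered tracked-person stream stored as parallel arrays.

    Frames are nominally spaced at ``1 / frame_rate``; missing frames are
    represented with ``person_present = False`` and NaN spatial fields.
    """

    def __init__(
        self,
        t: np.ndarray,
        person_present: np.ndarray,
        x: np.ndarray,
        y: np.ndarray,
        posture: np.ndarray,
        lfx: np.ndarray,
        lfy: np.ndarray,
        rfx: np.ndarray,
        rfy: np.ndarray,
        frame_rate: float,
    ) -> None:
        self.t = np.asarray(t, dtype=float)
        self.person_present = np.asarray(person_present, dtype=bool)
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.posture = np.asarray(posture, dtype=object)
        self.lfx = np.asarray(lfx, dtype=float)
        self.lfy = np.asarray(lfy, dtype=float)
        self.rfx = np.asarray(rfx, dtype=float)
        self.rfy = np.asarray(rfy, dtype=float)
        self.frame_rate = float(frame_rate)
        self.validate()

    # -- construction -------------------------------------------------

    @classmethod
    def from_frames(cls, frames: Sequence[TrackFrame], frame_rate: float) -> "TrackStream":
        n = len(frames)
        t = np.array([f.t for f in frames], dtype=float)
        present = np.array([f.person_present for f in frames], dtype=bool)

        def col(name: str) -> np.ndarray:
            return np.array(
                [getattr(f, name) if getattr(f, name) is not None else np.nan for f in frames],
                dtype=float,
            ) if n else np.empty(0)

        posture = np.array([f.posture for f in frames], dtype=object) if n else np.empty(0, object)
        return cls(t, present, col("x"), col("y"), posture,
                   col("lfx"), col("lfy"), col("rfx"), col("rfy"), frame_rate)

    @classmethod
    def empty(cls, frame_rate: float = 10.0) -> "TrackStream":
        z = np.empty(0)
        return cls(z, np.empty(0, bool), z, z, np.empty(0, object), z, z, z, z, frame_rate)

    # -- basic protocol ------------------------------------------------

    def __len__(self) -> int:
        return len(self.t)

    @property
    def dt(self) -> float:
        return 1.0 / self.frame_rate

    def validate(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if len(self.t) and np.any(np.diff(self.t) <= 0):
            raise ValueError("frame timestamps must be strictly increasing")
        if len(self.t) and self.t[0] < 0:
            raise ValueError("timestamps must be non-negative")
        for name in ("person_present", "x", "y", "posture", "lfx", "lfy", "rfx", "rfy"):
            if len(getattr(self, name)) != len(self.t):
                raise ValueError(f"column {name} length mismatch")
        present = self.person_present
        bad = present & np.array([p not in POSTURES for p in self.posture], dtype=bool)
        if bad.any():
            raise ValueError(f"unknown posture label {self.posture[bad][0]!r}")

    def slice_time(self, t_start: float, t_end: float) -> "TrackStream":
        """Restrict the stream to frames with ``t_start <= t < t_end``."""
        sel = (self.t >= t_start - 1e-9) & (self.t < t_end - 1e-9)
        return TrackStream(
            self.t[sel], self.person_present[sel], self.x[sel], self.y[sel],
            self.posture[sel], self.lfx[sel], self.lfy[sel],
            self.rfx[sel], self.rfy[sel], self.frame_rate,
        )


@dataclass(frozen=True)
class Zone:
    """A named contextual zone given as a simple floor-plane polygon (meters)."""

    name: str
    polygon: tuple

    def to_shapely(self) -> Polygon:
        if len(self.polygon) < 3:
            raise ValueError(f"zone {self.name!r}: polygon needs >= 3 vertices")
        poly = Polygon(self.polygon)
        if not poly.is_valid or not poly.is_simple:
            raise ValueError(f"zone {self.name!r}: polygon is not simple/valid")
        return poly

    @classmethod
    def rectangle(cls, name: str, x0: float, y0: float, x1: float, y1: float) -> "Zone":
        return cls(name, ((x0, y0), (x1, y0), (x1, y1), (x0, y1)))


@dataclass(frozen=True)
class PrimitiveStateInterval:
    state_name: str
    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise ValueError("t_start must be < t_end")


@dataclass(frozen=True)
class Constraint:
    """Temporal constraint of a composite event model.

    kinds:
      * ``overlap``             args: ``{"components": [alias, ...]}`` — all
        listed components active at the same instant.
      * ``min_duration_before`` args: ``{"component": alias, "seconds": d}`` —
        the component has been continuously active for at least ``d`` seconds.
    """

    kind: str
    args: dict

    KINDS = ("overlap", "min_duration_before")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown constraint kind {self.kind!r}")


@dataclass(frozen=True)
class EventModel:
    name: str
    components: dict  # alias -> primitive state name or other model name
    constraints: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "constraints", tuple(self.constraints))
        if len(set(self.components)) != len(self.components):
            raise ValueError(f"model {self.name!r}: duplicate component aliases")
        for c in self.constraints:
            refs = c.args.get("components", [c.args.get("component")])
            for alias in refs:
                if alias not in self.components:
                    raise ValueError(
                        f"model {self.name!r}: constraint references undeclared "
                        f"component {alias!r}"
                    )
        if not self.constraints:
            raise ValueError(f"model {self.name!r}: at least one constraint required")


@dataclass(frozen=True)
class EventInterval:
    model_name: str
    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise ValueError("t_start must be < t_end")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


# ---------------------------------------------------------------------------
# primitive-state detection
# ---------------------------------------------------------------------------


def _runs(mask: np.ndarray) -> list:
    """Index runs of True values as (start, stop) with stop exclusive."""
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def _mask_to_intervals(mask, t, dt, state_name, gap_merge_s):
    spans = [(t[i], t[j - 1] + dt) for i, j in _runs(mask)]
    merged: list = []
    for s, e in spans:
        if merged and s - merged[-1][1] < gap_merge_s - 1e-12:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return [PrimitiveStateInterval(state_name, s, e) for s, e in merged]


def detect_primitive_states(
    stream: TrackStream,
    zones: Iterable[Zone],
    gap_merge_s: float = DEFAULT_GAP_MERGE_S,
) -> list:
    """Detect maximal zone-occupancy and posture intervals.

    For every zone ``Z`` emits ``Person_in_zone_<Z>`` intervals during which
    the person's position lies inside (or on the boundary of) the zone
    polygon; for every posture ``P`` emits ``Person_<P>`` intervals.  Runs of
    the same state separated by less than ``gap_merge_s`` (tracking dropout)
    are merged.
    """
    zones = list(zones)
    polys = {}
    for z in zones:
        if z.name in polys:
            raise ValueError(f"duplicate zone name {z.name!r}")
        polys[z.name] = z.to_shapely()

    if len(stream) == 0 or not stream.person_present.any():
        return []

    present = stream.person_present
    t, dt = stream.t, stream.dt
    pts = shapely.points(np.column_stack([stream.x[present], stream.y[present]]))

    out: list = []
    for z in zones:
        inside = shapely.covers(polys[z.name], pts)  # boundary counts as inside
        mask = np.zeros(len(stream), dtype=bool)
        mask[present] = inside
        out.extend(_mask_to_intervals(mask, t, dt, f"Person_in_zone_{z.name}", gap_merge_s))
    for p in POSTURES:
        mask = present & (stream.posture == p)
        out.extend(_mask_to_intervals(mask, t, dt, f"Person_{p}", gap_merge_s))
    out.sort(key=lambda iv: (iv.state_name, iv.t_start))
    return out


# ---------------------------------------------------------------------------
# composite-event recognition
# ---------------------------------------------------------------------------


def _check_acyclic(models: dict) -> None:
    def depth(name: str, stack: tuple) -> int:
        if name not in models:
            return 0
        if name in stack:
            raise ValueError(f"cyclic model reference involving {name!r}")
        if len(stack) >= MAX_MODEL_DEPTH:
            raise ValueError(f"model nesting deeper than {MAX_MODEL_DEPTH}")
        m = models[name]
        return 1 + max((depth(ref, stack + (name,)) for ref in m.components.values()),
                       default=0)

    for name in models:
        depth(name, ())


def recognize_composite_events(
    models: Iterable[EventModel],
    primitives: Iterable[PrimitiveStateInterval],
    dt: float = 0.1,
) -> list:
    """Recognize composite events on the discrete frame grid.

    An event is active at a grid instant iff *all* of its constraints hold
    there; maximal active spans are emitted as :class:`EventInterval`.  The
    recognized interval begins at the first instant all constraints are
    satisfied and ends when any constraint ceases to hold.
    """
    models = list(models)
    primitives = list(primitives)
    model_map = {m.name: m for m in models}
    if len(model_map) != len(models):
        raise ValueError("duplicate model names")
    _check_acyclic(model_map)

    if not primitives:
        return []
    origin = min(iv.t_start for iv in primitives)
    t_max = max(iv.t_end for iv in primitives)
    n = int(round((t_max - origin) / dt))
    if n <= 0:
        return []

    state_act: dict = {}
    for iv in primitives:
        arr = state_act.setdefault(iv.state_name, np.zeros(n, dtype=bool))
        i = int(round((iv.t_start - origin) / dt))
        j = int(round((iv.t_end - origin) / dt))
        arr[max(i, 0):min(j, n)] = True

    model_act: dict = {}

    def activity(ref: str) -> np.ndarray:
        if ref in model_map:
            return model_activity(ref)
        return state_act.get(ref, np.zeros(n, dtype=bool))

    def model_activity(name: str) -> np.ndarray:
        if name in model_act:
            return model_act[name]
        m = model_map[name]
        comp = {alias: activity(ref) for alias, ref in m.components.items()}
        act = np.ones(n, dtype=bool)
        for c in m.constraints:
            if c.kind == "overlap":
                for alias in c.args["components"]:
                    act &= comp[alias]
            else:  # min_duration_before
                a = comp[c.args["component"]]
                idx = np.arange(n)
                last_inactive = np.maximum.accumulate(np.where(a, -1, idx))
                run = idx - last_inactive  # consecutive active frames ending at idx
                act &= a & ((run - 1) * dt >= c.args["seconds"] - 1e-9)
        model_act[name] = act
        return act

    out: list = []
    for m in models:
        act = model_activity(m.name)
        for i, j in _runs(act):
            out.append(EventInterval(m.name, origin + i * dt, origin + j * dt))
    out.sort(key=lambda iv: (iv.model_name, iv.t_start))
    return out


# ---------------------------------------------------------------------------
# detection evaluation
# ---------------------------------------------------------------------------


def _match_counts(rec: list, tru: list, threshold: float) -> tuple:
    """Greedy one-to-one matching by decreasing overlap; returns (tp, fp, fn)."""
    cands = []
    for ti, tv in enumerate(tru):
        tlen = tv.t_end - tv.t_start
        for ri, rv in enumerate(rec):
            ov = min(tv.t_end, rv.t_end) - max(tv.t_start, rv.t_start)
            if ov > 0 and ov >= threshold * tlen - 1e-12:
                cands.append((ov, ti, ri))
    cands.sort(key=lambda c: (-c[0], c[1], c[2]))
    used_t: set = set()
    used_r: set = set()
    tp = 0
    for ov, ti, ri in cands:
        if ti in used_t or ri in used_r:
            continue
        used_t.add(ti)
        used_r.add(ri)
        tp += 1
    return tp, len(rec) - tp, len(tru) - tp


def evaluate_detection(
    recognized: Iterable[EventInterval],
    truth: Iterable[EventInterval],
    threshold: float = 0.5,
) -> dict:
    """Per-model precision/recall of recognized intervals against ground truth.

    A recognized interval is a true positive iff a same-model truth interval
    overlaps it by at least ``threshold`` of the truth interval's length
    (one-to-one greedy matching by decreasing overlap).  ``recall`` is absent
    (``None``) for models without truth intervals, ``precision`` is absent for
    models without recognized intervals.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    recognized = list(recognized)
    truth = list(truth)
    names = sorted({iv.model_name for iv in recognized} | {iv.model_name for iv in truth})
    result = {}
    for name in names:
        rec = [iv for iv in recognized if iv.model_name == name]
        tru = [iv for iv in truth if iv.model_name == name]
        tp, fp, fn = _match_counts(rec, tru, threshold)
        result[name] = {
            "tp": tp,
            "fp": fp,
            "fn": fn,
            "precision": tp / (tp + fp) if rec else None,
            "recall": tp / (tp + fn) if tru else None,
        }
    return result


def evaluate_detection_pooled(pairs: Iterable[tuple], threshold: float = 0.5) -> dict:
    """Pool per-participant (recognized, truth) pairs into cohort-level scores.

    Matching is done within each pair; true/false positive and false negative
    counts are summed before computing precision and recall.
    """
    agg: dict = {}
    for recognized, truth in pairs:
        per = evaluate_detection(recognized, truth, threshold)
        for name, d in per.items():
            a = agg.setdefault(name, {"tp": 0, "fp": 0, "fn": 0, "n_rec": 0, "n_tru": 0})
            a["tp"] += d["tp"]
            a["fp"] += d["fp"]
            a["fn"] += d["fn"]
            a["n_rec"] += d["tp"] + d["fp"]
            a["n_tru"] += d["tp"] + d["fn"]
    out = {}
    for name, a in agg.items():
        out[name] = {
            "tp": a["tp"],
            "fp": a["fp"],
            "fn": a["fn"],
            "precision": a["tp"] / a["n_rec"] if a["n_rec"] else None,
            "recall": a["tp"] / a["n_tru"] if a["n_tru"] else None,
        }
    return out
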