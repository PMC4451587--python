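"""File formats: track CSV, zone/model JSON, event CSV, profile CSV.

All CSV files use comma separators, '.' decimals, UTF-8 and a mandatory
header row.  Track streams have one row per frame with empty spatial cells
when the person is absent.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd

from .events import (
    Constraint,
    EventInterval,
    EventModel,
    TrackStream,
    Zone,
)
from .profiles import BehavioralProfile, ProtocolSpec, ActivityUnit, default_protocol

__all__ = [
    "TRACK_COLUMNS",
    "read_track_csv",
    "write_track_csv",
    "read_zones_json",
    "write_zones_json",
    "read_models_json",
    "write_models_json",
    "read_events_csv",
    "write_events_csv",
    "read_profiles_csv",
    "write_profiles_csv",
    "read_protocol_json",
    "write_protocol_json",
    "roundtrip",
]

TRACK_COLUMNS = ("t", "person_present", "x", "y", "posture", "lfx", "lfy", "rfx", "rfy")

PathLike = Union[str, Path]


def _require_columns(df: pd.DataFrame, cols: Iterable[str], path: PathLike) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")


# -- track streams -----------------------------------------------------------


def read_track_csv(path: PathLike, frame_rate: Optional[float] = None) -> TrackStream:
    """Read a track stream; the frame rate is inferred from the median
    timestamp spacing unless given."""
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:  # carries the offending line number
        raise ValueError(f"{path}: malformed CSV ({exc})") from exc
    _require_columns(df, TRACK_COLUMNS, path)
    t = df["t"].to_numpy(dtype=float)
    if frame_rate is None:
        if len(t) < 2:
            raise ValueError(f"{path}: cannot infer frame rate from < 2 frames")
        frame_rate = 1.0 / float(np.median(np.diff(t)))
    present = df["person_present"].to_numpy(dtype=float).astype(bool)
    posture = np.array(
        [p if isinstance(p, str) and p else None for p in df["posture"].fillna("")],
        dtype=object,
    )
    cols = {c: df[c].to_numpy(dtype=float) for c in ("x", "y", "lfx", "lfy", "rfx", "rfy")}
    return TrackStream(t, present, cols["x"], cols["y"], posture,
                       cols["lfx"], cols["lfy"], cols["rfx"], cols["rfy"],
                       round(frame_rate, 6))


def write_track_csv(stream: TrackStream, path: PathLike) -> None:
    df = pd.DataFrame({
        "t": stream.t,
        "person_present": stream.person_present.astype(int),
        "x": stream.x,
        "y": stream.y,
        "posture": [p if p is not None else "" for p in stream.posture],
        "lfx": stream.lfx,
        "lfy": stream.lfy,
        "rfx": stream.rfx,
        "rfy": stream.rfy,
    })
    df.to_csv(path, index=False, float_format="%.6f")


# -- zones and event models --------------------------------------------------


def read_zones_json(path: PathLike) -> list:
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    zones = [Zone(z["name"], tuple(tuple(map(float, v)) for v in z["polygon"]))
             for z in data]
    for z in zones:
        z.to_shapely()  # validates
    return zones


def write_zones_json(zones: Iterable[Zone], path: PathLike) -> None:
    data = [{"name": z.name, "polygon": [list(v) for v in z.polygon]} for z in zones]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(data, fh, indent=1, sort_keys=True)


def read_models_json(path: PathLike) -> list:
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    return [
        EventModel(
            name=m["name"],
            components=dict(m["components"]),
            constraints=tuple(Constraint(c["kind"], dict(c["args"]))
                              for c in m["constraints"]),
        )
        for m in data
    ]


def write_models_json(models: Iterable[EventModel], path: PathLike) -> None:
    data = [
        {
            "name": m.name,
            "components": dict(m.components),
            "constraints": [{"kind": c.kind, "args": c.args} for c in m.constraints],
        }
        for m in models
    ]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(data, fh, indent=1, sort_keys=True)


# -- event intervals ---------------------------------------------------------


def read_events_csv(path: PathLike) -> "pd.DataFrame | list":
    """Read recognized/ground-truth events.

    Returns a list of :class:`EventInterval` for plain 3-column files; files
    with a ``participant_id`` column return a DataFrame.
    """
    df = pd.read_csv(path)
    _require_columns(df, ("model_name", "t_start", "t_end"), path)
    for i, row in df.iterrows():
        if not row["t_start"] < row["t_end"]:
            raise ValueError(f"{path}: line {i + 2}: t_start must be < t_end")
    if "participant_id" in df.columns:
        return df
    return [EventInterval(r.model_name, float(r.t_start), float(r.t_end))
            for r in df.itertuples()]


def write_events_csv(events, path: PathLike,
                     participant_ids: Optional[Iterable[str]] = None) -> None:
    """Write events; with ``participant_ids`` (parallel to ``events``) a
    4-column cohort file is produced."""
    rows = [
        {"model_name": e.model_name, "t_start": e.t_start, "t_end": e.t_end}
        for e in events
    ]
    df = pd.DataFrame(rows, columns=["model_name", "t_start", "t_end"])
    if participant_ids is not None:
        df.insert(0, "participant_id", list(participant_ids))
    df.to_csv(path, index=False, float_format="%.6f")


def events_from_dataframe(df: pd.DataFrame) -> dict:
    """Group a cohort event DataFrame into {participant_id: [EventInterval]}."""
    out: dict = {}
    for r in df.itertuples():
        out.setdefault(r.participant_id, []).append(
            EventInterval(r.model_name, float(r.t_start), float(r.t_end)))
    return out


# -- behavioral profiles -----------------------------------------------------


def write_profiles_csv(profiles: Iterable[BehavioralProfile], path: PathLike,
                       protocol: Optional[ProtocolSpec] = None) -> None:
    rows = [p.to_feature_row(protocol) for p in profiles]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6f")


def read_profiles_csv(path: PathLike,
                      protocol: Optional[ProtocolSpec] = None) -> list:
    """Parse profiles; column order is irrelevant (header-mapped)."""
    df = pd.read_csv(path)
    return [BehavioralProfile.from_feature_row(row, protocol)
            for row in df.to_dict(orient="records")]


# -- protocol ----------------------------------------------------------------


def read_protocol_json(path: PathLike) -> ProtocolSpec:
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    units = tuple(
        ActivityUnit(u["model_name"], int(u["expected_count"]),
                     float(u.get("min_completion_s", 10.0)),
                     u.get("stem", ""))
        for u in data["activity_units"]
    )
    return ProtocolSpec(units, float(data.get("window_s", 900.0)))


def write_protocol_json(protocol: ProtocolSpec, path: PathLike) -> None:
    data = {
        "window_s": protocol.window_s,
        "activity_units": [
            {
                "model_name": u.model_name,
                "expected_count": u.expected_count,
                "min_completion_s": u.min_completion_s,
                "stem": u.stem,
            }
            for u in protocol.activity_units
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(data, fh, indent=1, sort_keys=True)


# -- generic round-trip ------------------------------------------------------

_KINDS = {
    "tracks": (read_track_csv, write_track_csv),
    "zones": (read_zones_json, write_zones_json),
    "models": (read_models_json, write_models_json),
    "events": (read_events_csv, write_events_csv),
    "profiles": (read_profiles_csv, write_profiles_csv),
    "protocol": (read_protocol_json, write_protocol_json),
}


def roundtrip(path: PathLike, kind: str):
    """Parse a supported file, rewrite it in place, and return the object."""
    if kind not in _KINDS:
        raise ValueError(f"unsupported kind {kind!r}; one of {sorted(_KINDS)}")
    reader, writer = _KINDS[kind]
    obj = reader(path)
    if kind == "events" and isinstance(obj, pd.DataFrame):
        obj.to_csv(path, index=False, float_format="%.6f")
    else:
        writer(obj, path)
    return obj
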