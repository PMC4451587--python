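"""End-to-end pipeline: simulate -> recognize -> gait -> profile -> classify
-> evaluate -> stats, with a manifest of all written artifacts."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as eio
from .classify import (
    AUTONOMY_FEATURES,
    DIAGNOSIS_FEATURES,
    LabeledFeatureTable,
    cross_validate,
)
from .events import (
    EventInterval,
    TrackStream,
    detect_primitive_states,
    evaluate_detection_pooled,
    recognize_composite_events,
)
from .gait import GaitParameters, analyze_segment, extract_gait_segment
from .profiles import build_profile, default_protocol, stage_autonomy
from .scene import WALK_MODEL, assign_walk_tasks, default_event_models, default_zones
from .simulate import CohortConfig, NoiseConfig, simulate_cohort

logger = logging.getLogger("ecoassess.pipeline")

__all__ = ["PipelineConfig", "StageError", "run_full_pipeline", "recognize_stream"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name in the message."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


@dataclass
class PipelineConfig:
    output_dir: Path
    seed: int = 0
    frame_rate: float = 10.0
    dropout_prob: float = 0.0
    position_jitter_sd_m: float = 0.0
    folds: int = 20
    detection_threshold: float = 0.5
    composition: Optional[tuple] = None  # ((autonomy, diagnosis), count) pairs

    @classmethod
    def from_json(cls, path, output_dir: Optional[Path] = None,
                  seed: Optional[int] = None) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)
        comp = data.get("composition")
        if comp is not None:
            comp = tuple(sorted(((a, d), int(n)) for a, d, n in comp))
        cfg = cls(
            output_dir=Path(output_dir or data.get("output_dir", "pipeline_out")),
            seed=int(data.get("seed", 0)),
            frame_rate=float(data.get("frame_rate", 10.0)),
            dropout_prob=float(data.get("dropout_prob", 0.0)),
            position_jitter_sd_m=float(data.get("position_jitter_sd_m", 0.0)),
            folds=int(data.get("folds", 20)),
            detection_threshold=float(data.get("detection_threshold", 0.5)),
            composition=comp,
        )
        if seed is not None:
            cfg.seed = seed
        return cfg

    def cohort_config(self) -> CohortConfig:
        kwargs = dict(
            frame_rate=self.frame_rate,
            noise=NoiseConfig(self.dropout_prob, self.position_jitter_sd_m),
            seed=self.seed,
        )
        if self.composition is not None:
            kwargs["composition"] = self.composition
        return CohortConfig(**kwargs)


def recognize_stream(stream: TrackStream, zones=None, models=None) -> tuple:
    """Run primitive + composite recognition on one stream.

    Returns ``(primitives, events)`` where corridor-walk intervals are
    relabeled mono/dual by protocol order and the generic ``walking_task``
    intervals are dropped.
    """
    zones = zones if zones is not None else default_zones()
    models = models if models is not None else default_event_models()
    primitives = detect_primitive_states(stream, zones)
    raw = recognize_composite_events(models, primitives, dt=stream.dt)
    walks = assign_walk_tasks(raw)
    events = [e for e in raw if e.model_name != WALK_MODEL] + walks
    events.sort(key=lambda e: (e.model_name, e.t_start))
    return primitives, events


def _enclosing_corridor_interval(primitives, interval: EventInterval):
    """Expand a recognized walk interval to its corridor-occupancy span."""
    for p in primitives:
        if (p.state_name == "Person_in_zone_WalkCorridor"
                and p.t_start <= interval.t_start + 1e-9
                and interval.t_end <= p.t_end + 1e-9):
            return p.t_start, p.t_end
    return interval.t_start, interval.t_end


def _gait_for_participant(stream, primitives, events) -> dict:
    out = {}
    for kind, name in (("mono", "mono_task"), ("dual", "dual_task")):
        ivs = [e for e in events if e.model_name == name]
        if not ivs:
            raise StageError("gait", f"no recognized {name} interval")
        t0, t1 = _enclosing_corridor_interval(primitives, ivs[0])
        seg = extract_gait_segment(stream, t0, t1, kind)
        out[kind] = analyze_segment(seg)
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and return the run manifest (also written to disk).

    A second run with the same configuration produces byte-identical
    artifacts; every output file is listed in the manifest with its SHA-256.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "tracks").mkdir(exist_ok=True)
    zones = default_zones()
    models = default_event_models()
    protocol = default_protocol()
    files: list = []
    stages: list = []

    def done(stage: str) -> None:
        stages.append(stage)
        logger.info("stage %s: done", stage)

    # 1. simulate ---------------------------------------------------------
    try:
        cohort = simulate_cohort(config.cohort_config())
        gt_rows, label_rows = [], []
        for rec in cohort:
            path = out / "tracks" / f"{rec.schedule.participant_id}.csv"
            eio.write_track_csv(rec.stream, path)
            files.append(path)
            for ev in rec.gt_events:
                gt_rows.append((rec.schedule.participant_id, ev))
            s = rec.schedule
            label_rows.append({
                "participant_id": s.participant_id,
                "autonomy": s.autonomy,
                "diagnosis": s.diagnosis,
                "age": s.age,
                "scheduled_initiated": s.scheduled_initiated,
                "scheduled_completed": s.scheduled_completed,
                "iadl_window_start": s.iadl_window[0],
                "iadl_window_end": s.iadl_window[1],
            })
        eio.write_events_csv([ev for _, ev in gt_rows], out / "gt_events.csv",
                             participant_ids=[pid for pid, _ in gt_rows])
        pd.DataFrame(label_rows).to_csv(out / "labels.csv", index=False,
                                        float_format="%.6f")
        eio.write_zones_json(zones, out / "zones.json")
        eio.write_models_json(models, out / "models.json")
        eio.write_protocol_json(protocol, out / "protocol.json")
        files += [out / "gt_events.csv", out / "labels.csv", out / "zones.json",
                  out / "models.json", out / "protocol.json"]
        done("simulate")
    except StageError:
        raise
    except Exception as exc:
        raise StageError("simulate", str(exc)) from exc

    # 2. recognize ---------------------------------------------------------
    try:
        recognized: dict = {}
        prims: dict = {}
        rec_rows = []
        for rec in cohort:
            pid = rec.schedule.participant_id
            primitives, events = recognize_stream(rec.stream, zones, models)
            prims[pid] = primitives
            recognized[pid] = events
            rec_rows += [(pid, ev) for ev in events]
        eio.write_events_csv([ev for _, ev in rec_rows], out / "recognized_events.csv",
                             participant_ids=[pid for pid, _ in rec_rows])
        files.append(out / "recognized_events.csv")
        done("recognize")
    except Exception as exc:
        raise StageError("recognize", str(exc)) from exc

    # 3. gait --------------------------------------------------------------
    try:
        gait: dict = {}
        gait_rows = []
        for rec in cohort:
            pid = rec.schedule.participant_id
            gait[pid] = _gait_for_participant(rec.stream, prims[pid], recognized[pid])
            row = {"participant_id": pid}
            row.update(gait[pid]["mono"].to_feature_dict("single_task"))
            row.update(gait[pid]["dual"].to_feature_dict("dual_task"))
            gait_rows.append(row)
        pd.DataFrame(gait_rows).to_csv(out / "gait.csv", index=False,
                                       float_format="%.6f")
        files.append(out / "gait.csv")
        done("gait")
    except StageError:
        raise
    except Exception as exc:
        raise StageError("gait", str(exc)) from exc

    # 4. profile -----------------------------------------------------------
    try:
        protocol_models = {u.model_name for u in protocol.activity_units}
        profiles = []
        for rec in cohort:
            s = rec.schedule
            pid = s.participant_id
            iadl_events = [e for e in recognized[pid]
                           if e.model_name in protocol_models]
            profile = build_profile(
                iadl_events, gait[pid], protocol, s.age, pid,
                labels={"autonomy": s.autonomy, "diagnosis": s.diagnosis},
                window_start=s.iadl_window[0],
            )
            profile.labels["autonomy_staged"] = stage_autonomy(
                profile.activities_completed)
            profiles.append(profile)
        eio.write_profiles_csv(profiles, out / "profiles.csv", protocol)
        files.append(out / "profiles.csv")
        done("profile")
    except Exception as exc:
        raise StageError("profile", str(exc)) from exc

    # 5. classify ----------------------------------------------------------
    try:
        df = pd.DataFrame([p.to_feature_row(protocol) for p in profiles])
        reports = {}
        for task, feats, label in (
            ("autonomy", AUTONOMY_FEATURES, "autonomy"),
            ("diagnosis", DIAGNOSIS_FEATURES, "diagnosis"),
        ):
            table = LabeledFeatureTable.from_dataframe(df, feats, label)
            report = cross_validate(table, k=min(config.folds, table.n),
                                    seed=config.seed)
            reports[task] = {"features": list(feats), **report.to_dict()}
        with open(out / "classification.json", "w", encoding="utf-8") as fh:
            json.dump(reports, fh, indent=1, sort_keys=True)
        files.append(out / "classification.json")
        done("classify")
    except Exception as exc:
        raise StageError("classify", str(exc)) from exc

    # 6. evaluate ----------------------------------------------------------
    try:
        pairs = [(recognized[r.schedule.participant_id], r.gt_events) for r in cohort]
        pooled = evaluate_detection_pooled(pairs, config.detection_threshold)
        rows = [
            {"model_name": name, **{k: ("" if v is None else v)
                                    for k, v in d.items()}}
            for name, d in sorted(pooled.items())
        ]
        pd.DataFrame(rows).to_csv(out / "detection_eval.csv", index=False,
                                  float_format="%.6f")
        files.append(out / "detection_eval.csv")
        done("evaluate")
    except Exception as exc:
        raise StageError("evaluate", str(exc)) from exc

    # 7. stats -------------------------------------------------------------
    try:
        from .stats import group_comparison_table, spearman_table

        feats = ["age", "single_task_total_duration", "dual_task_total_duration",
                 "activities_initiated", "activities_completed"]
        cmp_table = group_comparison_table(
            df.assign(diagnosis=[p.labels["diagnosis"] for p in profiles]),
            "diagnosis", feats,
            pairs=[("HC", "MCI"), ("MCI", "AD"), ("HC", "AD")],
        )
        cmp_table.to_csv(out / "group_comparisons.csv")
        corr_table = spearman_table(
            df, ["activities_initiated", "activities_completed"],
            ["age", "single_task_total_duration", "dual_task_total_duration"],
        )
        corr_table.to_csv(out / "correlations.csv")
        files += [out / "group_comparisons.csv", out / "correlations.csv"]
        done("stats")
    except Exception as exc:
        raise StageError("stats", str(exc)) from exc

    manifest = {
        "seed": config.seed,
        "n_participants": len(cohort),
        "stages": stages,
        "files": {str(p.relative_to(out)): _sha256(p) for p in sorted(files)},
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
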