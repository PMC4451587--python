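"""Gait parameter extraction from walking-task track segments.

Steps are detected as local maxima of the inter-feet distance signal; when
foot coordinates are unavailable a centroid-speed fallback is provided.
Kinematic parameters (duration, step count, cadence, step-length statistics,
stride length, distance traveled, average speed and tracking-gap duration)
are computed per task segment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.signal import find_peaks

from .events import TrackStream

__all__ = [
    "MIN_STEP_SEPARATION_M",
    "MIN_STEP_INTERVAL_S",
    "FootDataError",
    "GaitSegment",
    "StepEvent",
    "GaitParameters",
    "detect_steps",
    "compute_gait_parameters",
    "extract_gait_segment",
    "analyze_segment",
]

#: Minimum inter-feet distance (meters) for a local maximum to count as a step.
MIN_STEP_SEPARATION_M = 0.15

#: Minimum time (seconds) between two consecutive detected steps.
MIN_STEP_INTERVAL_S = 0.3

#: Fraction of person-present frames that must carry foot coordinates.
MIN_FOOT_COVERAGE = 0.8


class FootDataError(ValueError):
    """Raised when a segment lacks foot data; advises the centroid fallback."""


@dataclass(frozen=True)
class StepEvent:
    t: float
    position: tuple  # (x, y) centroid at the step instant


@dataclass
class GaitSegment:
    """A track-stream slice covering one walking task."""

    stream: TrackStream
    task_kind: str = "mono"  # "mono" | "dual"

    def __post_init__(self) -> None:
        if self.task_kind not in ("mono", "dual"):
            raise ValueError(f"unknown task kind {self.task_kind!r}")
        if len(self.stream) == 0 or not self.stream.person_present.any():
            raise ValueError("gait segment has no person-present frames")

    def foot_coverage(self) -> float:
        present = self.stream.person_present
        have_feet = (
            present
            & ~np.isnan(self.stream.lfx) & ~np.isnan(self.stream.lfy)
            & ~np.isnan(self.stream.rfx) & ~np.isnan(self.stream.rfy)
        )
        return have_feet.sum() / present.sum()


def _interp_signal(t: np.ndarray, valid: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Fill invalid samples by linear interpolation over time."""
    if valid.all():
        return values
    return np.interp(t, t[valid], values[valid])


def detect_steps(
    segment: GaitSegment,
    min_step_separation_m: float = MIN_STEP_SEPARATION_M,
    min_step_interval_s: float = MIN_STEP_INTERVAL_S,
    centroid_fallback: bool = False,
) -> list:
    """Detect step events within a walking segment.

    Steps are local maxima of the inter-feet Euclidean distance exceeding
    ``min_step_separation_m`` and separated by at least
    ``min_step_interval_s``.  If more than 20% of the person-present frames
    lack foot coordinates a :class:`FootDataError` is raised unless
    ``centroid_fallback`` is set, in which case local minima of the centroid
    speed are used instead.
    """
    s = segment.stream
    present = s.person_present
    t = s.t
    min_dist_frames = max(1, int(round(min_step_interval_s * s.frame_rate)))

    if segment.foot_coverage() < MIN_FOOT_COVERAGE and not centroid_fallback:
        raise FootDataError(
            "foot coordinates missing in more than 20% of frames; "
            "re-run with centroid_fallback=True to use centroid-speed minima"
        )

    if segment.foot_coverage() >= MIN_FOOT_COVERAGE and not centroid_fallback:
        valid = (
            present
            & ~np.isnan(s.lfx) & ~np.isnan(s.lfy)
            & ~np.isnan(s.rfx) & ~np.isnan(s.rfy)
        )
        d = np.hypot(s.lfx - s.rfx, s.lfy - s.rfy)
        d = _interp_signal(t, valid, np.where(valid, d, 0.0))
        peaks, _ = find_peaks(d, height=min_step_separation_m, distance=min_dist_frames)
    else:
        valid = present & ~np.isnan(s.x) & ~np.isnan(s.y)
        x = _interp_signal(t, valid, np.where(valid, s.x, 0.0))
        y = _interp_signal(t, valid, np.where(valid, s.y, 0.0))
        if len(t) < 3:
            return []
        speed = np.hypot(np.gradient(x, t), np.gradient(y, t))
        # steps show as speed minima (double support); require real motion
        peaks, _ = find_peaks(-speed, distance=min_dist_frames)
        peaks = peaks[speed[peaks] < np.median(speed)]

    valid_xy = present & ~np.isnan(s.x) & ~np.isnan(s.y)
    xs = _interp_signal(t, valid_xy, np.where(valid_xy, s.x, 0.0))
    ys = _interp_signal(t, valid_xy, np.where(valid_xy, s.y, 0.0))
    return [StepEvent(float(t[i]), (float(xs[i]), float(ys[i]))) for i in peaks]


@dataclass(frozen=True)
class GaitParameters:
    """Kinematic summary of one walking task."""

    total_duration_s: float
    n_steps: int
    cadence: float  # steps / second
    step_lengths_m: tuple
    stride_length_m: float
    distance_traveled_m: float
    avg_speed_mps: float
    gap_duration_s: float
    step_len_mean_m: float
    step_len_sd_m: float
    step_len_max_m: float
    step_len_min_m: float

    def to_feature_dict(self, prefix: str) -> dict:
        """Flatten to named features; ``prefix`` is ``single_task``/``dual_task``."""
        return {
            f"{prefix}_total_duration": self.total_duration_s,
            f"{prefix}_gap_duration": self.gap_duration_s,
            f"{prefix}_number_of_steps": float(self.n_steps),
            f"{prefix}_cadence": self.cadence,
            f"{prefix}_average_steps": self.step_len_mean_m,
            f"{prefix}_standard_deviation_steps": self.step_len_sd_m,
            f"{prefix}_max_steps": self.step_len_max_m,
            f"{prefix}_min_steps": self.step_len_min_m,
            f"{prefix}_stride_length": self.stride_length_m,
            f"{prefix}_distance_traveled": self.distance_traveled_m,
            f"{prefix}_speed_average_from_centroid_information": self.avg_speed_mps,
        }

    FEATURE_SUFFIXES = (
        "total_duration", "gap_duration", "number_of_steps", "cadence",
        "average_steps", "standard_deviation_steps", "max_steps", "min_steps",
        "stride_length", "distance_traveled",
        "speed_average_from_centroid_information",
    )

    @classmethod
    def from_feature_dict(cls, prefix: str, row: dict) -> "GaitParameters":
        g = {suf: float(row[f"{prefix}_{suf}"]) for suf in cls.FEATURE_SUFFIXES}
        return cls(
            total_duration_s=g["total_duration"],
            n_steps=int(round(g["number_of_steps"])),
            cadence=g["cadence"],
            step_lengths_m=(),
            stride_length_m=g["stride_length"],
            distance_traveled_m=g["distance_traveled"],
            avg_speed_mps=g["speed_average_from_centroid_information"],
            gap_duration_s=g["gap_duration"],
            step_len_mean_m=g["average_steps"],
            step_len_sd_m=g["standard_deviation_steps"],
            step_len_max_m=g["max_steps"],
            step_len_min_m=g["min_steps"],
        )


def compute_gait_parameters(segment: GaitSegment, steps: list) -> GaitParameters:
    """Compute kinematic parameters for a walking segment.

    Step lengths are centroid displacements between consecutive step instants
    (n steps yield n - 1 lengths).  Distance traveled is the centroid
    polyline length over
    person-present frames; gap duration is the summed duration of frames with
    no person detection.
    """
    s = segment.stream
    t = s.t
    dt = s.dt
    total_duration = float(t[-1] - t[0] + dt)
    if total_duration <= 0:
        raise ValueError("zero-duration segment")

    for ev in steps:
        if not (t[0] - 1e-9 <= ev.t <= t[-1] + dt + 1e-9):
            raise ValueError("step event outside segment time bounds")

    present = s.person_present
    px, py = s.x[present], s.y[present]
    distance = float(np.hypot(np.diff(px), np.diff(py)).sum()) if present.sum() > 1 else 0.0
    gap = float((~present).sum() * dt)

    positions = [ev.position for ev in steps]
    lengths = tuple(
        float(np.hypot(x1 - x0, y1 - y0))
        for (x0, y0), (x1, y1) in zip(positions[:-1], positions[1:])
    )
    n_steps = len(steps)
    mean_len = float(np.mean(lengths)) if lengths else 0.0
    if n_steps >= 2:
        sd = float(np.std(lengths))
        mx, mn = float(np.max(lengths)), float(np.min(lengths))
    else:
        sd = mx = mn = 0.0

    return GaitParameters(
        total_duration_s=total_duration,
        n_steps=n_steps,
        cadence=n_steps / total_duration,
        step_lengths_m=lengths,
        stride_length_m=2.0 * mean_len,
        distance_traveled_m=distance,
        avg_speed_mps=distance / total_duration,
        gap_duration_s=gap,
        step_len_mean_m=mean_len,
        step_len_sd_m=sd,
        step_len_max_m=mx,
        step_len_min_m=mn,
    )


def extract_gait_segment(stream: TrackStream, t_start: float, t_end: float,
                         task_kind: str) -> GaitSegment:
    """Slice ``stream`` to ``[t_start, t_end)`` as a walking-task segment."""
    return GaitSegment(stream.slice_time(t_start, t_end), task_kind)


def analyze_segment(segment: GaitSegment, centroid_fallback: bool = False) -> GaitParameters:
    """Convenience: detect steps then compute parameters."""
    steps = detect_steps(segment, centroid_fallback=centroid_fallback)
    return compute_gait_parameters(segment, steps)
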