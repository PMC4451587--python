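import numpy as np
import pytest

from ecoassess.events import TrackFrame, TrackStream
from ecoassess.gait import (
    FootDataError,
    GaitParameters,
    GaitSegment,
    compute_gait_parameters,
    detect_steps,
)

from conftest import make_stream

FR = 10.0


def sinusoid_feet_stream(duration_s=10.0, period_s=1.0, amp=0.3, frame_rate=FR):
    """Standing still; inter-feet distance oscillates 0..amp with the given
    period (one peak per period)."""
    n = int(duration_s * frame_rate)
    t = np.arange(n) / frame_rate
    d = amp / 2 * (1 + np.sin(2 * np.pi * t / period_s))
    feet = [(((1.0 - di / 2), 1.0), ((1.0 + di / 2), 1.0)) for di in d]
    return make_stream([(1.0, 1.0)] * n, frame_rate=frame_rate, feet=feet)


def straight_walk_stream(length_m=4.0, duration_s=8.0, n_steps=8, frame_rate=FR,
                         present=None):
    """Uniform straight walk with triangular feet-distance bumps at the step
    instants (evenly spaced, first at half a step interval)."""
    n = int(duration_s * frame_rate)
    t = np.arange(n) / frame_rate
    x = length_m * t / duration_s
    gap = duration_s / n_steps
    steps = [(i + 0.5) * gap for i in range(n_steps)]
    d = np.full(n, 0.05)
    for s in steps:
        tri = np.clip(1 - np.abs(t - s) / (0.4 * gap), 0, 1)
        d = np.maximum(d, 0.05 + 0.30 * tri)
    feet = [((x[i] - d[i] / 2, 0.0), (x[i] + d[i] / 2, 0.0)) for i in range(n)]
    return make_stream([(xi, 0.0) for xi in x], frame_rate=frame_rate, feet=feet,
                       present=present), steps


class TestDetectSteps:
    def test_standing_still_no_steps(self):
        stream = make_stream([(1.0, 1.0)] * 50)  # constant 0.1 m feet distance
        seg = GaitSegment(stream, "mono")
        assert detect_steps(seg) == []

    def test_sinusoidal_signal_ten_steps(self):
        seg = GaitSegment(sinusoid_feet_stream(), "mono")
        steps = detect_steps(seg)
        assert len(steps) == 10

    def test_steps_time_ordered(self):
        stream, _ = straight_walk_stream()
        steps = detect_steps(GaitSegment(stream, "mono"))
        times = [s.t for s in steps]
        assert times == sorted(times)

    def test_scripted_steps_recovered_at_times(self):
        stream, scripted = straight_walk_stream(n_steps=8)
        steps = detect_steps(GaitSegment(stream, "mono"))
        assert len(steps) == 8
        for got, want in zip(steps, scripted):
            assert abs(got.t - want) <= 1.0 / FR + 1e-9

    def test_missing_feet_raises_with_advice(self):
        n = 50
        frames = [TrackFrame(i / FR, True, i * 0.1, 0.0, "standing")
                  for i in range(n)]
        stream = TrackStream.from_frames(frames, FR)
        with pytest.raises(FootDataError, match="centroid"):
            detect_steps(GaitSegment(stream, "mono"))

    def test_centroid_fallback_runs(self):
        n = 50
        frames = [TrackFrame(i / FR, True, i * 0.1, 0.0, "standing")
                  for i in range(n)]
        stream = TrackStream.from_frames(frames, FR)
        steps = detect_steps(GaitSegment(stream, "mono"), centroid_fallback=True)
        assert isinstance(steps, list)


class TestComputeGaitParameters:
    def test_straight_walk_arithmetic(self):
        stream, _ = straight_walk_stream(length_m=4.0, duration_s=8.0, n_steps=8)
        seg = GaitSegment(stream, "mono")
        steps = detect_steps(seg)
        params = compute_gait_parameters(seg, steps)
        assert params.n_steps == 8
        assert params.total_duration_s == pytest.approx(8.0)
        assert params.cadence == pytest.approx(1.0)
        assert params.avg_speed_mps == pytest.approx(0.5, rel=0.02)
        assert params.step_len_mean_m == pytest.approx(0.5, rel=0.05)
        assert params.stride_length_m == pytest.approx(1.0, rel=0.05)
        assert params.gap_duration_s == 0.0
        assert params.distance_traveled_m == pytest.approx(4.0, rel=0.02)

    def test_gap_duration_from_dropout(self):
        present = [True] * 80
        for i in range(30, 35):  # frames [3.0, 3.5) dropped
            present[i] = False
        stream, _ = straight_walk_stream(present=present)
        seg = GaitSegment(stream, "mono")
        params = compute_gait_parameters(seg, detect_steps(seg))
        assert params.gap_duration_s == pytest.approx(0.5)

    def test_step_stats_zero_below_two_steps(self):
        stream = make_stream([(1.0, 1.0)] * 20)
        seg = GaitSegment(stream, "mono")
        params = compute_gait_parameters(seg, [])
        assert params.n_steps == 0
        assert params.step_len_sd_m == params.step_len_max_m == params.step_len_min_m == 0.0
        assert params.stride_length_m == 0.0

    def test_step_outside_bounds_rejected(self):
        from ecoassess.gait import StepEvent

        stream = make_stream([(1.0, 1.0)] * 20)
        seg = GaitSegment(stream, "mono")
        with pytest.raises(ValueError, match="bounds"):
            compute_gait_parameters(seg, [StepEvent(99.0, (0, 0))])

    def test_invariant_relations(self):
        stream, _ = straight_walk_stream()
        seg = GaitSegment(stream, "mono")
        p = compute_gait_parameters(seg, detect_steps(seg))
        assert p.cadence == pytest.approx(p.n_steps / p.total_duration_s)
        assert p.stride_length_m == pytest.approx(2 * np.mean(p.step_lengths_m))
        assert p.distance_traveled_m >= max(p.step_lengths_m)


class TestProperties:
    @pytest.mark.parametrize("k", [0.5, 2.0, 3.7])
    def test_scale_equivariance(self, k):
        stream, _ = straight_walk_stream()
        seg = GaitSegment(stream, "mono")
        base = compute_gait_parameters(seg, detect_steps(seg))

        scaled_stream = TrackStream(
            stream.t, stream.person_present, stream.x * k, stream.y * k,
            stream.posture, stream.lfx * k, stream.lfy * k,
            stream.rfx * k, stream.rfy * k, stream.frame_rate)
        seg2 = GaitSegment(scaled_stream, "mono")
        # keep the same detected step instants: rescale detection threshold
        steps2 = detect_steps(seg2, min_step_separation_m=0.15 * k)
        scaled = compute_gait_parameters(seg2, steps2)

        assert scaled.n_steps == base.n_steps
        assert scaled.total_duration_s == pytest.approx(base.total_duration_s)
        assert scaled.cadence == pytest.approx(base.cadence)
        assert scaled.gap_duration_s == pytest.approx(base.gap_duration_s)
        assert scaled.step_len_mean_m == pytest.approx(k * base.step_len_mean_m)
        assert scaled.stride_length_m == pytest.approx(k * base.stride_length_m)
        assert scaled.distance_traveled_m == pytest.approx(k * base.distance_traveled_m)
        assert scaled.avg_speed_mps == pytest.approx(k * base.avg_speed_mps)

    @pytest.mark.parametrize("shift", [5.0, 123.4])
    def test_time_shift_invariance(self, shift):
        stream, _ = straight_walk_stream()
        seg = GaitSegment(stream, "mono")
        base = compute_gait_parameters(seg, detect_steps(seg))

        shifted = TrackStream(
            stream.t + shift, stream.person_present, stream.x, stream.y,
            stream.posture, stream.lfx, stream.lfy, stream.rfx, stream.rfy,
            stream.frame_rate)
        seg2 = GaitSegment(shifted, "mono")
        moved = compute_gait_parameters(seg2, detect_steps(seg2))
        for attr in ("total_duration_s", "n_steps", "cadence", "stride_length_m",
                     "distance_traveled_m", "avg_speed_mps", "gap_duration_s",
                     "step_len_mean_m", "step_len_sd_m"):
            assert getattr(moved, attr) == pytest.approx(getattr(base, attr))

    def test_feature_dict_roundtrip(self):
        stream, _ = straight_walk_stream()
        seg = GaitSegment(stream, "mono")
        p = compute_gait_parameters(seg, detect_steps(seg))
        row = p.to_feature_dict("single_task")
        q = GaitParameters.from_feature_dict("single_task", row)
        assert q.n_steps == p.n_steps
        assert q.total_duration_s == pytest.approx(p.total_duration_s)
        assert q.stride_length_m == pytest.approx(p.stride_length_m)


class TestCrossModule:
    def test_simulator_scripted_steps_recovered(self):
        """Noiseless rendered walks yield exactly the scripted step counts and
        the dual task is slower than the single task when scheduled so."""
        from ecoassess.simulate import generate_schedule, render_track_stream
        from ecoassess.gait import extract_gait_segment, analyze_segment

        rng = np.random.default_rng(42)
        sched = generate_schedule("p", "good", "HC", rng)
        stream, _ = render_track_stream(sched)
        for walk, kind in ((sched.walk_mono, "mono"), (sched.walk_dual, "dual")):
            seg = extract_gait_segment(stream, walk.t_entry, walk.t_exit, kind)
            params = analyze_segment(seg)
            assert params.n_steps == walk.n_steps
            assert params.total_duration_s == pytest.approx(walk.duration, abs=0.11)
        assert sched.walk_dual.duration >= sched.walk_mono.duration

    def test_simulator_distance_matches_path_length(self):
        from ecoassess.simulate import generate_schedule, render_track_stream
        from ecoassess.gait import extract_gait_segment, analyze_segment

        rng = np.random.default_rng(7)
        for _ in range(20):
            sched = generate_schedule("p", "intermediate", "MCI", rng)
            stream, _ = render_track_stream(sched)
            walk = sched.walk_mono
            seg = extract_gait_segment(stream, walk.t_entry, walk.t_exit, "mono")
            params = analyze_segment(seg)
            path_len = float(np.hypot(walk.end_pos[0] - walk.start_pos[0],
                                      walk.end_pos[1] - walk.start_pos[1]))
            assert params.distance_traveled_m == pytest.approx(path_len, rel=0.02)
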