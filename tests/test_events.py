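import numpy as np
import pytest
from matplotlib.path import Path as MplPath

from ecoassess.events import (
    Constraint,
    EventInterval,
    EventModel,
    PrimitiveStateInterval,
    TrackStream,
    Zone,
    detect_primitive_states,
    evaluate_detection,
    recognize_composite_events,
)

from conftest import make_stream

DT = 0.1


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def rle_oracle(mask, t, dt, gap_merge_s=0.5):
    """Run-length encode a per-frame boolean scan, merging short gaps."""
    spans = []
    start = None
    for i, m in enumerate(mask):
        if m and start is None:
            start = t[i]
        elif not m and start is not None:
            spans.append((start, t[i - 1] + dt))
            start = None
    if start is not None:
        spans.append((start, t[-1] + dt))
    merged = []
    for s, e in spans:
        if merged and s - merged[-1][1] < gap_merge_s - 1e-12:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def primitive_oracle(stream, zones):
    """Brute-force per-frame point-in-polygon scan + RLE."""
    out = {}
    t = stream.t
    for z in zones:
        path = MplPath(np.asarray(z.polygon, dtype=float))
        mask = []
        for i in range(len(stream)):
            if not stream.person_present[i]:
                mask.append(False)
                continue
            pt = (stream.x[i], stream.y[i])
            mask.append(bool(path.contains_point(pt, radius=1e-9)
                             or path.contains_point(pt, radius=-1e-9)))
        out[f"Person_in_zone_{z.name}"] = rle_oracle(mask, t, stream.dt)
    for p in ("standing", "sitting", "bending"):
        mask = [bool(stream.person_present[i] and stream.posture[i] == p)
                for i in range(len(stream))]
        out[f"Person_{p}"] = rle_oracle(mask, t, stream.dt)
    return {k: v for k, v in out.items() if v}


def composite_oracle(models, primitives, dt=DT):
    """Instant-wise brute-force constraint evaluation + RLE."""
    if not primitives:
        return []
    origin = min(iv.t_start for iv in primitives)
    t_max = max(iv.t_end for iv in primitives)
    n = int(round((t_max - origin) / dt))
    instants = origin + np.arange(n) * dt
    by_state = {}
    for iv in primitives:
        by_state.setdefault(iv.state_name, []).append((iv.t_start, iv.t_end))
    model_map = {m.name: m for m in models}
    model_intervals = {}

    def merge_spans(spans):
        # continuity is over the union of a component's intervals
        out = []
        for s, e in sorted(spans):
            if out and s <= out[-1][1] + 1e-9:
                out[-1] = (out[-1][0], max(out[-1][1], e))
            else:
                out.append((s, e))
        return out

    def intervals_of(ref):
        if ref in model_map:
            return solve(ref)
        return merge_spans(by_state.get(ref, []))

    def active_at(spans, t):
        return any(s - 1e-9 <= t < e - 1e-9 for s, e in spans)

    def duration_at(spans, t):
        for s, e in spans:
            if s - 1e-9 <= t < e - 1e-9:
                return t - s
        return -1.0

    def solve(name):
        if name in model_intervals:
            return model_intervals[name]
        m = model_map[name]
        comp = {alias: intervals_of(ref) for alias, ref in m.components.items()}
        mask = []
        for t in instants:
            ok = True
            for c in m.constraints:
                if c.kind == "overlap":
                    ok = ok and all(active_at(comp[a], t) for a in c.args["components"])
                else:
                    ok = ok and duration_at(comp[c.args["component"]], t) >= (
                        c.args["seconds"] - 1e-9)
                if not ok:
                    break
            mask.append(ok)
        spans = rle_oracle(mask, instants, dt, gap_merge_s=0.0)
        model_intervals[name] = spans
        return spans

    out = []
    for m in models:
        for s, e in solve(m.name):
            out.append(EventInterval(m.name, s, e))
    out.sort(key=lambda iv: (iv.model_name, iv.t_start))
    return out


def random_primitives(rng, n_intervals, states, t_max=20.0):
    out = []
    for _ in range(n_intervals):
        s = round(rng.uniform(0, t_max - 0.5), 1)
        e = round(s + rng.uniform(0.2, 4.0), 1)
        out.append(PrimitiveStateInterval(rng.choice(states), s, e))
    return out


def random_models(rng, states, n_models=3):
    models = []
    for i in range(n_models):
        comps = {f"c{j}": str(rng.choice(states)) for j in range(rng.integers(2, 4))}
        cons = [Constraint("overlap", {"components": list(comps)})]
        if rng.random() < 0.7:
            cons.append(Constraint("min_duration_before", {
                "component": str(rng.choice(list(comps))),
                "seconds": float(rng.choice([0.2, 0.5, 1.0, 2.0])),
            }))
        models.append(EventModel(f"m{i}", comps, tuple(cons)))
    if n_models >= 2 and rng.random() < 0.5:
        # one nested model referencing the first
        comps = {"c0": "m0", "c1": str(rng.choice(states))}
        models.append(EventModel("nested", comps, (
            Constraint("overlap", {"components": ["c0", "c1"]}),
        )))
    return models


# ---------------------------------------------------------------------------
# primitive-state detection
# ---------------------------------------------------------------------------


class TestDetectPrimitiveStates:
    def test_constant_state_stream(self):
        zone = Zone.rectangle("Drink", 0.0, 0.0, 2.0, 2.0)
        stream = make_stream([(1.0, 1.0)] * 100)  # 10 s at 10 Hz
        got = detect_primitive_states(stream, [zone])
        assert got == [
            PrimitiveStateInterval("Person_in_zone_Drink", 0.0, 10.0),
            PrimitiveStateInterval("Person_standing", 0.0, 10.0),
        ]

    def test_empty_stream(self):
        zone = Zone.rectangle("Z", 0, 0, 1, 1)
        assert detect_primitive_states(TrackStream.empty(), [zone]) == []

    def test_all_absent_stream(self):
        zone = Zone.rectangle("Z", 0, 0, 1, 1)
        stream = make_stream([(0, 0)] * 10, present=[False] * 10)
        assert detect_primitive_states(stream, [zone]) == []

    def test_malformed_polygon_names_zone(self):
        bowtie = Zone("Bad", ((0, 0), (1, 1), (1, 0), (0, 1)))
        stream = make_stream([(0.5, 0.5)] * 5)
        with pytest.raises(ValueError, match="Bad"):
            detect_primitive_states(stream, [bowtie])

    def test_too_few_vertices(self):
        with pytest.raises(ValueError, match="3 vertices"):
            Zone("Line", ((0, 0), (1, 1))).to_shapely()

    def test_duplicate_zone_names(self):
        z = Zone.rectangle("Z", 0, 0, 1, 1)
        stream = make_stream([(0.5, 0.5)] * 5)
        with pytest.raises(ValueError, match="duplicate"):
            detect_primitive_states(stream, [z, z])

    def test_gap_merge(self):
        # 0.3 s dropout inside a zone run is merged; 1 s gap is not
        zone = Zone.rectangle("Z", 0, 0, 1, 1)
        present = [True] * 10 + [False] * 3 + [True] * 10
        stream = make_stream([(0.5, 0.5)] * 23, present=present)
        got = [iv for iv in detect_primitive_states(stream, [zone])
               if iv.state_name == "Person_in_zone_Z"]
        assert [(iv.t_start, round(iv.t_end, 9)) for iv in got] == [(0.0, 2.3)]

        present = [True] * 10 + [False] * 10 + [True] * 10
        stream = make_stream([(0.5, 0.5)] * 30, present=present)
        got = [iv for iv in detect_primitive_states(stream, [zone])
               if iv.state_name == "Person_in_zone_Z"]
        assert [(round(iv.t_start, 9), round(iv.t_end, 9)) for iv in got] == [
            (0.0, 1.0), (2.0, 3.0)]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        zones = [Zone.rectangle("A", 0.5, 0.5, 2.0, 2.0),
                 Zone.rectangle("B", 2.5, 0.0, 4.0, 1.5)]
        postures = rng.choice(["standing", "sitting", "bending"], size=200)
        pos = rng.uniform(0, 4.2, size=(200, 2))
        present = rng.random(200) > 0.05
        stream = make_stream([tuple(p) for p in pos], posture=list(postures),
                             present=present)
        got = detect_primitive_states(stream, zones)
        want = primitive_oracle(stream, zones)
        got_map = {}
        for iv in got:
            got_map.setdefault(iv.state_name, []).append(
                (round(iv.t_start, 6), round(iv.t_end, 6)))
        want = {k: [(round(s, 6), round(e, 6)) for s, e in v]
                for k, v in want.items()}
        assert got_map == want


# ---------------------------------------------------------------------------
# composite recognition
# ---------------------------------------------------------------------------


def prepare_drink_model():
    return EventModel(
        "Prepare Drink",
        {"c1": "Person_in_zone_Drink", "c2": "Person_bending"},
        (
            Constraint("overlap", {"components": ["c1", "c2"]}),
            Constraint("min_duration_before", {"component": "c1", "seconds": 2.0}),
        ),
    )


class TestRecognizeCompositeEvents:
    def test_prepare_drink_example(self):
        prims = [
            PrimitiveStateInterval("Person_in_zone_Drink", 0.0, 10.0),
            PrimitiveStateInterval("Person_bending", 3.0, 4.0),
        ]
        got = recognize_composite_events([prepare_drink_model()], prims, dt=DT)
        assert got == [EventInterval("Prepare Drink", 3.0, 4.0)]

    def test_min_duration_never_satisfied(self):
        prims = [
            PrimitiveStateInterval("Person_in_zone_Drink", 0.0, 1.0),
            PrimitiveStateInterval("Person_bending", 0.0, 1.0),
        ]
        assert recognize_composite_events([prepare_drink_model()], prims, dt=DT) == []

    def test_event_starts_when_duration_reached(self):
        # bending throughout: recognition begins exactly at the 2 s mark
        prims = [
            PrimitiveStateInterval("Person_in_zone_Drink", 0.0, 10.0),
            PrimitiveStateInterval("Person_bending", 0.0, 10.0),
        ]
        got = recognize_composite_events([prepare_drink_model()], prims, dt=DT)
        assert got == [EventInterval("Prepare Drink", 2.0, 10.0)]

    def test_undeclared_component_rejected(self):
        with pytest.raises(ValueError, match="undeclared"):
            EventModel("M", {"c1": "S"},
                       (Constraint("overlap", {"components": ["c1", "cX"]}),))

    def test_cycle_detection(self):
        a = EventModel("A", {"c": "B"},
                       (Constraint("min_duration_before",
                                   {"component": "c", "seconds": 0.0}),))
        b = EventModel("B", {"c": "A"},
                       (Constraint("min_duration_before",
                                   {"component": "c", "seconds": 0.0}),))
        prims = [PrimitiveStateInterval("S", 0.0, 1.0)]
        with pytest.raises(ValueError, match="cyclic"):
            recognize_composite_events([a, b], prims, dt=DT)

    def test_no_primitives(self):
        assert recognize_composite_events([prepare_drink_model()], [], dt=DT) == []

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_instantwise_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        states = [f"S{i}" for i in range(4)]
        prims = random_primitives(rng, int(rng.integers(5, 50)), states)
        models = random_models(rng, states)
        got = recognize_composite_events(models, prims, dt=DT)
        want = composite_oracle(models, prims, dt=DT)
        assert [(iv.model_name, round(iv.t_start, 6), round(iv.t_end, 6))
                for iv in got] == \
               [(iv.model_name, round(iv.t_start, 6), round(iv.t_end, 6))
                for iv in want]

    @pytest.mark.parametrize("seed", range(10))
    def test_recognized_within_component_union(self, seed):
        rng = np.random.default_rng(200 + seed)
        states = [f"S{i}" for i in range(3)]
        prims = random_primitives(rng, 30, states)
        models = random_models(rng, states, n_models=2)
        got = recognize_composite_events(models, prims, dt=DT)
        model_map = {m.name: m for m in models}
        for iv in got:
            refs = set()

            def collect(name):
                for ref in model_map[name].components.values():
                    if ref in model_map:
                        collect(ref)
                    else:
                        refs.add(ref)

            collect(iv.model_name)
            union = [(p.t_start, p.t_end) for p in prims if p.state_name in refs]
            ts = np.arange(iv.t_start, iv.t_end - 1e-9, DT)
            for t in ts:
                assert any(s - 1e-9 <= t < e - 1e-9 for s, e in union)

    def test_idempotent(self, rng):
        states = ["S0", "S1"]
        prims = random_primitives(rng, 30, states)
        models = random_models(rng, states, n_models=2)
        a = recognize_composite_events(models, prims, dt=DT)
        b = recognize_composite_events(models, prims, dt=DT)
        assert a == b


# ---------------------------------------------------------------------------
# detection evaluation
# ---------------------------------------------------------------------------


class TestEvaluateDetection:
    def test_perfect_detection(self):
        evs = [EventInterval("m", 0, 5), EventInterval("m", 7, 9),
               EventInterval("k", 1, 2)]
        res = evaluate_detection(evs, evs, 0.5)
        for name in ("m", "k"):
            assert res[name]["precision"] == 1.0
            assert res[name]["recall"] == 1.0

    def test_empty_recognized(self):
        truth = [EventInterval("m", 0, 5)]
        res = evaluate_detection([], truth, 0.5)
        assert res["m"]["recall"] == 0.0
        assert res["m"]["precision"] is None

    def test_no_truth_for_model(self):
        rec = [EventInterval("m", 0, 5)]
        res = evaluate_detection(rec, [], 0.5)
        assert res["m"]["recall"] is None
        assert res["m"]["precision"] == 0.0

    def test_hand_counted_matching(self):
        truth = [EventInterval("m", 0, 10)]
        rec = [EventInterval("m", 0, 9), EventInterval("m", 20, 25)]
        res = evaluate_detection(rec, truth, 0.5)
        assert res["m"] == {"tp": 1, "fp": 1, "fn": 0,
                            "precision": 0.5, "recall": 1.0}

    def test_one_to_one_matching(self):
        # two recognized overlapping the same truth: only one TP
        truth = [EventInterval("m", 0, 10)]
        rec = [EventInterval("m", 0, 8), EventInterval("m", 1, 9)]
        res = evaluate_detection(rec, truth, 0.5)
        assert res["m"]["tp"] == 1 and res["m"]["fp"] == 1

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            evaluate_detection([], [], 0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_bounds(self, seed):
        rng = np.random.default_rng(seed)
        rec = [EventInterval("m", s, s + rng.uniform(0.5, 3))
               for s in rng.uniform(0, 30, 10)]
        tru = [EventInterval("m", s, s + rng.uniform(0.5, 3))
               for s in rng.uniform(0, 30, 8)]
        res = evaluate_detection(rec, tru, 0.5)["m"]
        assert 0.0 <= res["precision"] <= 1.0
        assert 0.0 <= res["recall"] <= 1.0
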