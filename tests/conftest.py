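import numpy as np
import pytest

from ecoassess.events import TrackFrame, TrackStream


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_stream(positions, frame_rate=10.0, posture="standing", feet=None,
                present=None):
    """Build a stream from a list of (x, y) centroid positions.

    ``feet`` optionally gives per-frame ((lfx, lfy), (rfx, rfy)); ``present``
    optionally flags person presence per frame.
    """
    frames = []
    dt = 1.0 / frame_rate
    for i, pos in enumerate(positions):
        ok = True if present is None else bool(present[i])
        if not ok:
            frames.append(TrackFrame(i * dt, False))
            continue
        x, y = pos
        p = posture[i] if isinstance(posture, (list, tuple, np.ndarray)) else posture
        if feet is not None:
            (lfx, lfy), (rfx, rfy) = feet[i]
        else:
            lfx, lfy, rfx, rfy = x - 0.05, y, x + 0.05, y
        frames.append(TrackFrame(i * dt, True, x, y, p, lfx, lfy, rfx, rfy))
    return TrackStream.from_frames(frames, frame_rate)


@pytest.fixture
def small_cohort_config():
    """One participant per (autonomy, diagnosis) cell — 7 participants."""
    from ecoassess.simulate import CohortConfig, TABLE_COMPOSITION

    comp = tuple(sorted((pair, 1) for pair in TABLE_COMPOSITION))
    return CohortConfig(composition=comp, seed=3)
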