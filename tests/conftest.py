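import numpy as np
import pytest

from gazentropy.io import AOIRegion, Fixation, TrialRecord


@pytest.fixture
def unit_layout():
    """Three disjoint 100x100 rectangles side by side, ids 1..3."""
    return [
        AOIRegion(1, "left", 0, 0, 100, 100),
        AOIRegion(2, "mid", 100, 0, 200, 100),
        AOIRegion(3, "right", 200, 0, 300, 100),
    ]


def make_trial(points, participant="P1", trial="T1", difficulty="Easy", comm="High",
               duration=100.0):
    """Trial with one fixation per (x, y) point, 200 ms apart."""
    fx = [
        Fixation(onset_ms=200.0 * k, duration_ms=duration, x_px=float(x), y_px=float(y))
        for k, (x, y) in enumerate(points)
    ]
    return TrialRecord(
        participant_id=participant, trial_id=trial, difficulty=difficulty,
        comm_frequency=comm, fixations=fx,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
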