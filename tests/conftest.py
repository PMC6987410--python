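import numpy as np
import pytest

from hippocal.model import DffTrace, SpikeTrain, forward_model

FRAME_RATE = 15.0
DURATION = 200.0


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_train(frames_and_counts, n_frames=int(DURATION * FRAME_RATE), frame_rate=FRAME_RATE):
    """Spike train with given {frame: count} placements."""
    counts = np.zeros(n_frames, dtype=np.int64)
    for frame, c in frames_and_counts.items():
        counts[frame] = c
    return SpikeTrain(counts=counts, frame_rate=frame_rate)


def noiseless_dff(train, **kwargs):
    """Exact forward-model dF/F trace for a train (baseline 1)."""
    y = forward_model(train, **kwargs)
    return DffTrace(values=y - 1.0, frame_rate=train.frame_rate, baseline_f0=1.0)
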