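import numpy as np
import pytest

from neodev.io import FluorescenceRecording
from neodev.normalize import DffRecording


@pytest.fixture
def small_recording() -> FluorescenceRecording:
    """3 cells x 10 frames with simple positive traces."""
    rng = np.random.default_rng(42)
    raw = 10.0 + rng.uniform(0, 1, size=(3, 10))
    coords = np.array([[10.0, 20.0], [100.0, 200.0], [300.0, 400.0]])
    return FluorescenceRecording(raw, coords, 30.0, "green", {"animal": "synthA"})


def make_dff(matrix, frame_rate=30.0, coords=None) -> DffRecording:
    matrix = np.asarray(matrix, dtype=float)
    if coords is None:
        coords = np.zeros((matrix.shape[0], 2))
    return DffRecording(matrix, frame_rate, np.asarray(coords, dtype=float))


def boxcar_event_dff(
    n_cells=10,
    n_frames=600,
    onset=200,
    duration=60,
    amplitude=1.0,
    participants=None,
    frame_rate=30.0,
) -> DffRecording:
    """Noiseless dF/F with one boxcar transient in a chosen cell subset."""
    dff = np.zeros((n_cells, n_frames))
    if participants is None:
        participants = np.arange(n_cells)
    dff[np.asarray(participants), onset:onset + duration] = amplitude
    return make_dff(dff, frame_rate)
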