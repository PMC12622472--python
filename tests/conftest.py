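import numpy as np
import pytest

from ganzfeld.config import AnalysisConfig
from ganzfeld.datatypes import AXES, EYES, GazeRecording


@pytest.fixture
def config() -> AnalysisConfig:
    return AnalysisConfig()


def make_gaze(
    t: np.ndarray,
    angle: float | np.ndarray = 0.0,
    pupil: float | np.ndarray = 50.0,
    missing=None,
) -> GazeRecording:
    """Constant-or-array gaze recording; ``missing`` is a boolean selector
    blanking all four coordinates."""
    n = len(t)
    base = np.broadcast_to(np.asarray(angle, float), (n,)).copy()
    pup = np.broadcast_to(np.asarray(pupil, float), (n,)).copy()
    angles = {(eye, axis): base.copy() for eye in EYES for axis in AXES}
    valid = {eye: np.ones(n, bool) for eye in EYES}
    if missing is not None:
        for eye in EYES:
            valid[eye][missing] = False
            for axis in AXES:
                angles[(eye, axis)][missing] = np.nan
    return GazeRecording(
        timestamp_s=t,
        angles=angles,
        pupil_area={eye: pup.copy() for eye in EYES},
        valid=valid,
    )
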