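import numpy as np
import pytest

from eecquant.atlas import Precursor
from eecquant.detection import DetectedObject


def make_objects(areas, intensities=None):
    """DetectedObjects with given areas and optional (mean_a, mean_b) pairs."""
    intensities = intensities or [(1.0, 1.0)] * len(areas)
    return [
        DetectedObject(object_id=i, centroid=(0.0, 0.0), area=a, mean_intensity=tuple(m))
        for i, (a, m) in enumerate(zip(areas, intensities))
    ]


@pytest.fixture
def ghrelin_like_precursor():
    """A short prohormone-like sequence: signal region, dibasic sites, a variant."""
    seq = "MLSSKAFLLLVLLALSGEGRRGSSFLSPSQKPQGRRAHQEDKVESFEEL"
    return Precursor(
        id="ghrl_like",
        sequence=seq,
        variants=[(25, "F", "L"), (40, "E", "D")],
        regions=[("signal", 1, 18), ("functional", 23, 34)],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
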