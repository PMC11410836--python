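import numpy as np
import pytest

from halluxmetry.geometry import BONES, AxisAnnotation, AxisSegment
from halluxmetry.phantoms import PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def square_annotation():
    """A hand-placed six-axis annotation on a 512x512 canvas, near-vertical axes."""
    segs = {
        "PH1": AxisSegment("PH1", (180.0, 205.0), (160.0, 140.0)),
        "MT1": AxisSegment("MT1", (170.0, 400.0), (178.0, 220.0)),
        "MT2": AxisSegment("MT2", (220.0, 400.0), (210.0, 230.0)),
        "MT3": AxisSegment("MT3", (270.0, 400.0), (255.0, 240.0)),
        "MT4": AxisSegment("MT4", (320.0, 400.0), (300.0, 250.0)),
        "MT5": AxisSegment("MT5", (370.0, 400.0), (340.0, 260.0)),
    }
    return AxisAnnotation(image_height=512, image_width=512, side="right",
                          segments=segs)


@pytest.fixture
def phantom_sample():
    """One deterministic 128x128 phantom with its ground-truth annotation."""
    spec = PhantomSpec(image_height=128, image_width=128, side="right",
                       true_HVA=-25.0, true_IMA=-12.0, seed=7)
    return generate_phantom(spec)


def segment_at(angle_deg: float, length: float, center=(256.0, 256.0),
               bone: str = "MT2") -> AxisSegment:
    """A segment of the given y-up inclination centered on ``center``."""
    phi = np.radians(angle_deg)
    dx, dy = np.cos(phi) * length / 2, -np.sin(phi) * length / 2
    return AxisSegment(bone, (center[0] - dx, center[1] - dy),
                       (center[0] + dx, center[1] + dy))
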