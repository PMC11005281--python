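import numpy as np
import pytest

from limbalign.geometry import LimbLandmarks, Point2D


def neutral_limb(side: str = "left") -> LimbLandmarks:
    """Perfectly aligned synthetic limb: vertical collinear mechanical axes,
    horizontal parallel joint lines -> HKA=0, JCLA=0, mLDFA=mMPTA=90."""
    x0 = 100.0
    pts = {
        "v1": Point2D(x0, 100.0),   # femoral head
        "v2": Point2D(x0, 300.0),   # femoral shaft centre (AMA = 0 here)
        "v3": Point2D(x0 + 40.0, 500.0),  # lateral condyle (left: lateral=+x)
        "v4": Point2D(x0, 500.0),   # knee centre, femoral side
        "v5": Point2D(x0 - 40.0, 500.0),  # medial condyle
        "v6": Point2D(x0 + 40.0, 510.0),  # lateral plateau
        "v7": Point2D(x0, 510.0),   # knee centre, tibial side
        "v8": Point2D(x0 - 40.0, 510.0),  # medial plateau
        "v9": Point2D(x0, 700.0),   # tibial shaft centre
        "v10": Point2D(x0, 900.0),  # ankle centre
    }
    if side == "right":  # mirror so lateral stays anatomically correct
        pts = {k: Point2D(200.0 - p.x, p.y) for k, p in pts.items()}
    return LimbLandmarks(side=side, pixel_spacing_mm=0.2, **pts)


@pytest.fixture
def neutral_left() -> LimbLandmarks:
    return neutral_limb("left")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
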