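import numpy as np
import pytest

from hipmorph import HipPair, HipSchema, HipSpec, LandmarkSet, generate_hip
from hipmorph.landmarks import default_schema


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def toy_schema():
    """A minimal 20-point schema for hand-constructed geometric examples."""
    return HipSchema(
        n_points=20,
        points={
            "TEARDROP_CAUDAL": 0,
            "SOURCIL_MEDIAL": 1,
            "SOURCIL_LATERAL": 2,
            "ACETAB_LATERAL_EDGE": 3,
            "FEMORAL_HEAD_APEX": 7,
        },
        segments={
            "HEAD_CONTOUR": (4, 10),
            "HEADNECK_SUPERIOR_CONTOUR": (10, 12),
            "NECK_LATERAL": (12, 14),
            "NECK_MEDIAL": (14, 16),
            "SHAFT_LATERAL": (16, 18),
            "SHAFT_MEDIAL": (18, 20),
        },
    )


def toy_points():
    """A geometrically sensible filling of the toy schema (canonical frame).

    Head circle center (0, 0), radius 50; neck axis pointing lateral-inferior
    at 45 degrees; vertical shaft.  Tests overwrite the landmarks they need.
    """
    pts = np.zeros((20, 2))
    pts[0] = (-80.0, -20.0)  # teardrop
    pts[1] = (-50.0, 45.0)   # medial sourcil
    pts[2] = (20.0, 52.0)    # lateral sourcil
    pts[3] = (30.0, 55.0)    # lateral bony edge
    # head contour on the circle r=50, away from the lateral-inferior neck
    for i, ang in enumerate((230.0, 180.0, 135.0, 90.0, 45.0, 10.0)):
        pts[4 + i] = 50.0 * np.array([np.cos(np.radians(ang)), np.sin(np.radians(ang))])
    n = np.array([1.0, -1.0]) / np.sqrt(2)  # neck axis direction
    m = np.array([1.0, 1.0]) / np.sqrt(2)
    pts[10] = 55.0 * np.cos(np.radians(40)) * n + 55.0 * np.sin(np.radians(40)) * m
    pts[11] = 58.0 * np.cos(np.radians(30)) * n + 58.0 * np.sin(np.radians(30)) * m
    pts[12] = 60.0 * n + 25.0 * m
    pts[13] = 75.0 * n + 25.0 * m
    pts[14] = 60.0 * n - 25.0 * m
    pts[15] = 75.0 * n - 25.0 * m
    pts[16] = (90.0, -60.0)
    pts[17] = (90.0, -120.0)
    pts[18] = (50.0, -60.0)
    pts[19] = (50.0, -120.0)
    return pts


def toy_set(pts=None, side="left"):
    return LandmarkSet(toy_points() if pts is None else pts, side=side,
                       image_id="toy", frame="canonical")


@pytest.fixture()
def default_pair(schema):
    pair, truth = generate_hip(HipSpec(), image_id="fixture")
    return pair, truth


def transform_pair(pair: HipPair, fn, swap_sides: bool = False) -> HipPair:
    """Apply a point transform to both hips; optionally swap side roles (mirror)."""

    def mk(lset: LandmarkSet, side: str) -> LandmarkSet:
        return LandmarkSet(fn(lset.points), side=side, image_id=lset.image_id)

    if swap_sides:
        return HipPair(left=mk(pair.right, "left"), right=mk(pair.left, "right"))
    return HipPair(left=mk(pair.left, "left"), right=mk(pair.right, "right"))
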