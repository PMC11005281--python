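"""Angle kernel, limb measurement and alignment classification."""

import math

import numpy as np
import pytest

from limbalign.geometry import (
    AlignmentClass,
    InvalidGeometryError,
    LimbLandmarks,
    Point2D,
    classify_alignment,
    measure_limb,
    signed_angle_between,
)

from conftest import neutral_limb


def _rotate(coords, centre, deg):
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    rot = np.array([[c, -s], [s, c]])
    return (rot @ (coords - centre).T).T + centre


class TestSignedAngle:
    def test_identical_directions_zero(self):
        assert signed_angle_between((0, 1), (0, 1)) == 0.0

    def test_orthogonal_magnitude(self):
        a = signed_angle_between((0, 1), (1, 0))
        assert abs(a) == pytest.approx(90.0)
        # declared convention: atan2 of the cross product; (0,1)->(1,0) has
        # cross = -1, so the rotation is negative
        assert a == pytest.approx(-90.0)

    def test_small_angle_magnitude(self):
        v = (math.sin(math.radians(5)), math.cos(math.radians(5)))
        assert abs(signed_angle_between((0, 1), v)) == pytest.approx(5.0, abs=1e-12)

    def test_matches_arctangent_oracle_on_random_pairs(self, rng):
        # oracle: rotate u's polar angle onto v's, wrap to (-180, 180]
        for _ in range(1000):
            u, v = rng.normal(size=2), rng.normal(size=2)
            if np.hypot(*u) < 1e-6 or np.hypot(*v) < 1e-6:
                continue
            expected = math.degrees(
                math.atan2(v[1], v[0]) - math.atan2(u[1], u[0])
            )
            if expected > 180:
                expected -= 360
            elif expected <= -180:
                expected += 360
            assert signed_angle_between(u, v) == pytest.approx(expected, abs=1e-9)

    def test_zero_vector_raises(self):
        with pytest.raises(InvalidGeometryError):
            signed_angle_between((0, 0), (1, 0))


class TestMeasureLimb:
    def test_neutral_limb_all_angles(self, neutral_left):
        a = measure_limb(neutral_left)
        assert a.hka == pytest.approx(0.0, abs=1e-12)
        assert a.jcla == pytest.approx(0.0, abs=1e-12)
        assert a.mldfa == pytest.approx(90.0, abs=1e-12)
        assert a.mmpta == pytest.approx(90.0, abs=1e-12)

    @pytest.mark.parametrize("side", ["left", "right"])
    def test_tibia_rotated_medially_gives_varus(self, side):
        # rotation-matrix oracle: swing the distal tibia (v9, v10) 5 deg
        # about v7 towards the medial side; the ankle ends up medial of the
        # femoral axis, i.e. the knee apex is lateral -> varus, HKA = -5
        lm = neutral_limb(side)
        coords = lm.as_array()
        lat = 1.0 if side == "left" else -1.0
        v7 = coords[6]
        # +deg in _rotate moves a point below the centre towards -x, which
        # is medial exactly when lat=+1; scale by lat for the right limb
        coords[[8, 9]] = _rotate(coords[[8, 9]], v7, 5.0 * lat)
        moved = measure_limb(LimbLandmarks.from_array(coords, side, 0.2))
        assert moved.hka == pytest.approx(-5.0, abs=1e-9)

    def test_ama_by_rotation_construction(self, neutral_left):
        # construct v2 by rotating a point on the mechanical axis 6 deg
        # about v4; the construction itself is the oracle
        coords = neutral_left.as_array()
        v4 = coords[3]
        on_axis = coords[1]  # v2 currently on the mechanical axis
        coords[1] = _rotate(on_axis[None], v4, 6.0)[0]
        a = measure_limb(LimbLandmarks.from_array(coords, "left", 0.2))
        assert a.ama == pytest.approx(6.0, abs=1e-9)

    def test_mirror_symmetry(self, rng):
        for _ in range(50):
            coords = neutral_limb("left").as_array()
            coords += rng.normal(scale=5.0, size=coords.shape)
            coords[0, 1] -= 50  # keep v1 above v4 above v10
            coords[9, 1] += 50
            left = measure_limb(LimbLandmarks.from_array(coords, "left", 0.2))
            mirrored = coords.copy()
            mirrored[:, 0] = 200.0 - mirrored[:, 0]
            right = measure_limb(LimbLandmarks.from_array(mirrored, "right", 0.2))
            for k, v in left.as_dict().items():
                assert v == pytest.approx(getattr(right, k), abs=1e-9), k

    def test_rigid_rotation_invariance(self, rng):
        coords = neutral_limb("left").as_array()
        coords += rng.normal(scale=5.0, size=coords.shape)
        base = measure_limb(LimbLandmarks.from_array(coords, "left", 0.2))
        for deg in (-20.0, -3.0, 7.0, 15.0):
            rot = _rotate(coords, np.array([100.0, 500.0]), deg)
            a = measure_limb(LimbLandmarks.from_array(rot, "left", 0.2))
            for k, v in base.as_dict().items():
                assert v == pytest.approx(getattr(a, k), abs=1e-9), k

    def test_scale_invariance(self, rng):
        coords = neutral_limb("left").as_array()
        coords += rng.normal(scale=5.0, size=coords.shape)
        base = measure_limb(LimbLandmarks.from_array(coords, "left", 0.2))
        for s in (0.01, 0.5, 3.0, 1000.0):
            a = measure_limb(LimbLandmarks.from_array(coords * s, "left", 0.2))
            for k, v in base.as_dict().items():
                assert v == pytest.approx(getattr(a, k), abs=1e-9), k

    def test_degenerate_axis_named(self, neutral_left):
        coords = neutral_left.as_array()
        coords[9] = coords[6] + [0, 1e-12]  # v10 == v7 -> but ordering fails first
        coords[9] = coords[6]
        with pytest.raises((InvalidGeometryError, ValueError)):
            measure_limb(LimbLandmarks.from_array(coords, "left", 0.2))
        coords = neutral_left.as_array()
        coords[2] = coords[4]  # v3 == v5: degenerate femoral joint line
        with pytest.raises(InvalidGeometryError, match="femoral joint line"):
            measure_limb(LimbLandmarks.from_array(coords, "left", 0.2))


class TestClassification:
    @pytest.mark.parametrize(
        "hka,expected",
        [
            (-3.0, AlignmentClass.VARUS),
            (-2.0, AlignmentClass.VARUS),   # boundary inclusive
            (-1.999, AlignmentClass.NEUTRAL),
            (0.0, AlignmentClass.NEUTRAL),
            (1.999, AlignmentClass.NEUTRAL),
            (2.0, AlignmentClass.VALGUS),   # boundary inclusive
            (8.5, AlignmentClass.VALGUS),
        ],
    )
    def test_thresholds(self, hka, expected):
        assert classify_alignment(hka) is expected

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            classify_alignment(float("nan"))


class TestLandmarkInvariants:
    def test_vertical_ordering_enforced(self, neutral_left):
        coords = neutral_left.as_array()
        coords[0, 1] = 950.0  # femoral head below ankle
        with pytest.raises(InvalidGeometryError):
            LimbLandmarks.from_array(coords, "left", 0.2)

    def test_bad_side_rejected(self, neutral_left):
        with pytest.raises(ValueError):
            LimbLandmarks.from_array(neutral_left.as_array(), "both", 0.2)

    def test_nonfinite_point_rejected(self):
        with pytest.raises(InvalidGeometryError):
            Point2D(float("nan"), 0.0)
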