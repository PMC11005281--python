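"""Clinical alignment geometry for one lower limb.

Ten landmarks per limb, named after the anatomy they mark on an
anteroposterior long-leg radiograph:

    v1   centre of the femoral head
    v2   centre of the femoral diaphysis
    v3   lowest point of the lateral femoral condyle (or prosthesis)
    v4   centre of the knee joint, femoral side
    v5   lowest point of the medial femoral condyle (or prosthesis)
    v6   lowest point of the lateral tibial plateau (or prosthesis)
    v7   centre of the knee joint, tibial side
    v8   lowest point of the medial tibial plateau (or prosthesis)
    v9   centre of the tibial diaphysis
    v10  centre of the ankle joint

From these the five standard alignment measures are constructed:

    HKA    hip-knee-ankle angle: femoral mechanical axis (v1->v4) vs tibial
           mechanical axis (v7->v10); 0 deg = neutral, negative = varus.
    JCLA   joint line convergence angle: femoral condylar line (v3-v5) vs
           tibial plateau line (v6-v8); positive = the lines converge
           medially (the joint gap opens laterally).
    AMA    anatomical-mechanical angle of the femur: shaft axis (v2->v4) vs
           mechanical axis (v1->v4); unsigned.
    mLDFA  mechanical lateral distal femoral angle: the angle on the lateral
           side between the femoral mechanical axis (pointing proximally)
           and the femoral joint line.
    mMPTA  mechanical medial proximal tibial angle: the angle on the medial
           side between the tibial mechanical axis (pointing distally) and
           the tibial joint line.

All computations are done in image coordinates (x rightwards, y downwards).
Lateral/medial are resolved from the ``side`` label, never from the
x-ordering of the landmarks: on a conventionally displayed AP radiograph the
patient's left limb appears on the image right, so its lateral side is +x;
for the right limb lateral is -x.  A mislabelled side therefore produces
loudly wrong mLDFA/mMPTA rather than silently flipped ones.

v9 (tibial diaphysis centre) is carried and validated but participates in
none of the five angles.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, fields

import numpy as np

__all__ = [
    "Point2D",
    "LimbLandmarks",
    "AlignmentAngles",
    "AlignmentClass",
    "InvalidGeometryError",
    "LANDMARK_NAMES",
    "signed_angle_between",
    "measure_limb",
    "classify_alignment",
    "lateral_sign",
]

LANDMARK_NAMES = tuple(f"v{i}" for i in range(1, 11))

#: HKA thresholds for the varus / neutral / valgus classes (degrees),
#: boundary inclusive: varus iff HKA <= -2, valgus iff HKA >= +2.
VARUS_THRESHOLD_DEG = -2.0
VALGUS_THRESHOLD_DEG = 2.0


class InvalidGeometryError(ValueError):
    """A landmark configuration that defines no usable axis or joint line."""


@dataclass(frozen=True)
class Point2D:
    """A landmark location in image coordinates (pixels, y increases down)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise InvalidGeometryError(f"non-finite point ({self.x}, {self.y})")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


@dataclass(frozen=True)
class LimbLandmarks:
    """The ten landmarks of one limb plus side label and pixel spacing."""

    v1: Point2D
    v2: Point2D
    v3: Point2D
    v4: Point2D
    v5: Point2D
    v6: Point2D
    v7: Point2D
    v8: Point2D
    v9: Point2D
    v10: Point2D
    side: str  # "left" | "right"
    pixel_spacing_mm: float | None = None  # None = unknown (portable photo)

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        if self.pixel_spacing_mm is not None and not self.pixel_spacing_mm > 0:
            raise ValueError("pixel_spacing_mm must be positive or None")
        if not (self.v1.y < self.v4.y < self.v10.y):
            raise InvalidGeometryError(
                "expected femoral head above knee above ankle "
                f"(v1.y={self.v1.y}, v4.y={self.v4.y}, v10.y={self.v10.y})"
            )

    def point(self, name: str) -> Point2D:
        if name not in LANDMARK_NAMES:
            raise KeyError(name)
        return getattr(self, name)

    def as_array(self) -> np.ndarray:
        """(10, 2) array of (x, y) in v1..v10 order."""
        return np.array([[p.x, p.y] for p in self.points()], dtype=float)

    def points(self) -> tuple[Point2D, ...]:
        return tuple(getattr(self, n) for n in LANDMARK_NAMES)

    @classmethod
    def from_array(
        cls,
        coords: np.ndarray,
        side: str,
        pixel_spacing_mm: float | None = None,
    ) -> "LimbLandmarks":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (10, 2):
            raise ValueError(f"expected (10, 2) coordinates, got {coords.shape}")
        pts = {n: Point2D(float(x), float(y)) for n, (x, y) in zip(LANDMARK_NAMES, coords)}
        return cls(side=side, pixel_spacing_mm=pixel_spacing_mm, **pts)


@dataclass(frozen=True)
class AlignmentAngles:
    """The five alignment angles in degrees.

    ``hka`` and ``jcla`` are signed (varus / lateral convergence negative,
    see module docstring); ``ama`` is unsigned; ``mldfa`` and ``mmpta`` are
    interior angles in (0, 180).
    """

    hka: float
    jcla: float
    ama: float
    mldfa: float
    mmpta: float

    def __post_init__(self) -> None:
        if not (abs(self.hka) < 90 and abs(self.jcla) < 90):
            raise ValueError("HKA and JCLA must lie in (-90, 90) degrees")
        if not 0 <= self.ama < 90:
            raise ValueError("AMA must lie in [0, 90) degrees")
        if not (0 < self.mldfa < 180 and 0 < self.mmpta < 180):
            raise ValueError("mLDFA and mMPTA must lie in (0, 180) degrees")

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


class AlignmentClass(enum.Enum):
    VARUS = "varus"
    NEUTRAL = "neutral"
    VALGUS = "valgus"


def lateral_sign(side: str) -> float:
    """Direction of the lateral side along image x for the given limb.

    On a conventionally displayed AP radiograph the patient's left limb is on
    the image right, so lateral is +x for "left" and -x for "right".
    """
    if side == "left":
        return 1.0
    if side == "right":
        return -1.0
    raise ValueError(f"unknown side {side!r}")


def _vec(a: Point2D, b: Point2D, what: str) -> np.ndarray:
    v = b.as_array() - a.as_array()
    if np.hypot(*v) < 1e-9:
        raise InvalidGeometryError(f"degenerate {what}: landmarks coincide")
    return v


def signed_angle_between(u, v) -> float:
    """Signed angle in degrees rotating direction ``u`` onto ``v``.

    Returned in (-180, 180]; the magnitude equals arccos of the normalised
    dot product.  The sign follows atan2 of the 2D cross product in the
    coordinate frame the inputs live in: in image coordinates (y down) a
    positive angle is a clockwise rotation as displayed on screen.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.hypot(*u) < 1e-12 or np.hypot(*v) < 1e-12:
        raise InvalidGeometryError("zero-length direction vector")
    cross = u[0] * v[1] - u[1] * v[0]
    dot = u[0] * v[0] + u[1] * v[1]
    ang = math.degrees(math.atan2(cross, dot))
    if ang <= -180.0:  # atan2 returns (-180, 180]; guard the open end
        ang += 360.0
    return ang


def _unsigned_angle(u: np.ndarray, v: np.ndarray) -> float:
    return abs(signed_angle_between(u, v))


def measure_limb(landmarks: LimbLandmarks) -> AlignmentAngles:
    """Compute the five alignment angles from the ten landmarks.

    Axis constructions: femoral mechanical axis v1->v4, tibial mechanical
    axis v7->v10, femoral anatomical (shaft) axis v2->v4, femoral joint line
    through v3/v5, tibial joint line through v6/v8.

    Raises :class:`InvalidGeometryError` when any axis-defining landmark
    pair coincides, naming the degenerate axis.
    """
    lm = landmarks
    lat = lateral_sign(lm.side)

    fem_mech = _vec(lm.v1, lm.v4, "femoral mechanical axis (v1-v4)")
    tib_mech = _vec(lm.v7, lm.v10, "tibial mechanical axis (v7-v10)")
    fem_anat = _vec(lm.v2, lm.v4, "femoral anatomical axis (v2-v4)")
    # joint lines oriented medial -> lateral
    fem_joint_lat = _vec(lm.v5, lm.v3, "femoral joint line (v3-v5)")
    tib_joint_lat = _vec(lm.v8, lm.v6, "tibial joint line (v6-v8)")

    # HKA: signed angle between the mechanical axes, sign fixed so that a
    # laterally deviating knee (varus) is negative regardless of side.
    hka = -lat * signed_angle_between(fem_mech, tib_mech)

    # JCLA: difference of the joint-line inclinations measured going
    # lateral (positive = sloping downwards towards lateral).  Positive
    # JCLA = tibial line drops away from the femoral line laterally, i.e.
    # the lines converge medially.
    alpha_f = math.degrees(math.atan2(fem_joint_lat[1], lat * fem_joint_lat[0]))
    alpha_t = math.degrees(math.atan2(tib_joint_lat[1], lat * tib_joint_lat[0]))
    jcla = alpha_t - alpha_f
    if jcla > 180.0:
        jcla -= 360.0
    elif jcla <= -180.0:
        jcla += 360.0

    ama = _unsigned_angle(fem_anat, fem_mech)

    # mLDFA: lateral-side angle at the knee between the mechanical axis
    # pointing proximally and the joint line pointing laterally.
    mldfa = _unsigned_angle(-fem_mech, fem_joint_lat)
    # mMPTA: medial-side angle between the mechanical axis pointing
    # distally and the plateau line pointing medially.
    mmpta = _unsigned_angle(tib_mech, -tib_joint_lat)

    return AlignmentAngles(hka=hka, jcla=jcla, ama=ama, mldfa=mldfa, mmpta=mmpta)


def classify_alignment(hka: float) -> AlignmentClass:
    """Varus / neutral / valgus from HKA, boundaries inclusive.

    varus iff HKA <= -2 deg, valgus iff HKA >= +2 deg, neutral otherwise.
    """
    if not math.isfinite(hka):
        raise ValueError("HKA must be finite")
    if hka <= VARUS_THRESHOLD_DEG:
        return AlignmentClass.VARUS
    if hka >= VALGUS_THRESHOLD_DEG:
        return AlignmentClass.VALGUS
    return AlignmentClass.NEUTRAL
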