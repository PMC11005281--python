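"""Synthetic AP long-leg radiograph phantoms with exact ground truth.

Generates stylised two-bone limb images whose ten landmarks are placed by
an analytic construction that inverts the angle definitions of
:mod:`limbalign.geometry`: given target HKA, AMA, mLDFA and mMPTA the
mechanical axes and joint lines are laid out so that ``measure_limb`` on
the returned landmarks reproduces the requested angles to numerical
precision.

The five angles are not mutually independent: the landmark construction
satisfies the closure identity

    JCLA = mMPTA - mLDFA - HKA

(in this package's sign conventions), so the cohort sampler draws HKA, AMA,
mLDFA and mMPTA and derives JCLA.  Clinically this loads severe HKA
deformity onto joint-line convergence, consistent with joint-space
collapse in advanced osteoarthritis.

Bone morphology is stylised (capsule shafts, disc femoral head, condylar
arcs), not anatomical: the phantoms exercise the measurement pipeline, they
do not emulate radiographic realism.  The optional "photo" capture mode
emulates re-photographing a film with a handheld device: a small rigid
similarity pose jitter (rotation capped at 2 degrees, applied identically
to image and landmarks so relative angles are untouched), vignetting, mild
blur and sensor noise.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

from .geometry import AlignmentClass, LimbLandmarks, lateral_sign, measure_limb

__all__ = [
    "PhantomSpec",
    "PhantomSample",
    "CohortParams",
    "sample_spec",
    "render",
    "make_dataset",
    "load_dataset",
]

#: Alignment-class mixture matching the knee-OA cohort the generator
#: emulates: 54.5% varus, 30.7% neutral, 14.8% valgus.
DEFAULT_CLASS_WEIGHTS = {"varus": 0.545, "neutral": 0.307, "valgus": 0.148}

#: HKA bands per class (degrees, varus negative).
DEFAULT_HKA_BANDS = {
    "varus": (-12.0, -2.0),
    "neutral": (-2.0, 2.0),
    "valgus": (2.0, 12.0),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic limb; angles in degrees."""

    hka_true: float
    jcla_true: float
    ama_true: float
    mldfa_true: float
    mmpta_true: float
    side: str = "left"
    has_prosthesis: bool = False
    image_height: int = 1024
    image_width: int = 416
    noise_sd: float = 0.02  # sensor noise sd on the [0, 1] intensity scale
    capture_degradation: str = "none"  # "none" | "photo"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be left/right, got {self.side!r}")
        if self.capture_degradation not in ("none", "photo"):
            raise ValueError("capture_degradation must be 'none' or 'photo'")
        if not (abs(self.hka_true) < 90 and abs(self.jcla_true) < 90):
            raise ValueError("HKA/JCLA out of range")
        if not 0 <= self.ama_true < 90:
            raise ValueError("AMA out of range")
        if not (0 < self.mldfa_true < 180 and 0 < self.mmpta_true < 180):
            raise ValueError("mLDFA/mMPTA out of range")
        expected_jcla = self.mmpta_true - self.mldfa_true - self.hka_true
        if abs(self.jcla_true - expected_jcla) > 1e-6:
            raise ValueError(
                "inconsistent spec: JCLA must equal mMPTA - mLDFA - HKA "
                f"({expected_jcla:.4f}), got {self.jcla_true:.4f}"
            )


@dataclass
class PhantomSample:
    image: np.ndarray  # (H, W) float in [0, 1]
    landmarks: LimbLandmarks
    spec: PhantomSpec


@dataclass(frozen=True)
class CohortParams:
    """Mixture weights and angle distributions for the cohort sampler."""

    class_weights: tuple[float, float, float] = (
        DEFAULT_CLASS_WEIGHTS["varus"],
        DEFAULT_CLASS_WEIGHTS["neutral"],
        DEFAULT_CLASS_WEIGHTS["valgus"],
    )
    hka_bands: tuple[tuple[float, float], ...] = (
        DEFAULT_HKA_BANDS["varus"],
        DEFAULT_HKA_BANDS["neutral"],
        DEFAULT_HKA_BANDS["valgus"],
    )
    ama_mean: float = 6.0  # conventional normative centres, degrees
    ama_sd: float = 1.0
    mldfa_mean: float = 88.0
    mldfa_sd: float = 1.5
    mmpta_mean: float = 87.0
    mmpta_sd: float = 1.5
    prosthesis_fraction: float = 0.358  # 146 of 408 joints in the emulated cohort
    photo_fraction: float = 0.0
    noise_sd: float = 0.02
    image_height: int = 1024
    image_width: int = 416

    def __post_init__(self) -> None:
        w = np.asarray(self.class_weights, dtype=float)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("class weights must be non-negative and sum to 1")


def sample_spec(params: CohortParams, rng: np.random.Generator) -> PhantomSpec:
    """Draw one phantom specification from the cohort distributions.

    The alignment class is drawn from the mixture weights, HKA uniformly
    within the class band, AMA/mLDFA/mMPTA from clipped normals, and JCLA
    from the closure identity (see module docstring).
    """
    cls = int(rng.choice(3, p=np.asarray(params.class_weights, dtype=float)))
    lo, hi = params.hka_bands[cls]
    hka = float(rng.uniform(lo, hi))
    ama = float(np.clip(rng.normal(params.ama_mean, params.ama_sd), 0.5, 15.0))
    mldfa = float(np.clip(rng.normal(params.mldfa_mean, params.mldfa_sd), 75.0, 105.0))
    mmpta = float(np.clip(rng.normal(params.mmpta_mean, params.mmpta_sd), 75.0, 105.0))
    jcla = mmpta - mldfa - hka
    side = "left" if rng.random() < 0.5 else "right"
    return PhantomSpec(
        hka_true=hka,
        jcla_true=jcla,
        ama_true=ama,
        mldfa_true=mldfa,
        mmpta_true=mmpta,
        side=side,
        has_prosthesis=bool(rng.random() < params.prosthesis_fraction),
        image_height=params.image_height,
        image_width=params.image_width,
        noise_sd=params.noise_sd,
        capture_degradation="photo" if rng.random() < params.photo_fraction else "none",
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def _dir(angle_deg: float) -> np.ndarray:
    a = math.radians(angle_deg)
    return np.array([math.cos(a), math.sin(a)])


def _ang(v: np.ndarray) -> float:
    return math.degrees(math.atan2(v[1], v[0]))


def _build_landmarks(spec: PhantomSpec) -> np.ndarray:
    """Place v1..v10 analytically from the spec angles; (10, 2) array."""
    H, W = spec.image_height, spec.image_width
    lat = lateral_sign(spec.side)

    L = 0.88 * H  # hip-to-ankle span in pixels
    L_f, L_t = 0.52 * L, 0.46 * L
    gap = 0.015 * L  # knee joint gap
    w_f = 0.055 * L  # condylar half-width
    w_t = 0.050 * L  # plateau half-width

    # split the HKA deformity evenly between femoral and tibial axis tilt;
    # tilts are measured lateral-positive from the vertical
    theta_f = -spec.hka_true / 2.0
    theta_t = spec.hka_true / 2.0
    f = np.array([lat * math.sin(math.radians(theta_f)), math.cos(math.radians(theta_f))])
    t = np.array([lat * math.sin(math.radians(theta_t)), math.cos(math.radians(theta_t))])

    v4 = np.array([W / 2.0, 0.06 * H + L_f])
    v1 = v4 - L_f * f
    v7 = v4 + np.array([0.0, gap])
    v10 = v7 + L_t * t
    v9 = v7 + 0.5 * L_t * t

    # femoral anatomical (shaft) axis: proximal direction rotated towards
    # lateral by AMA relative to the proximal mechanical direction
    anat_prox = _dir(_ang(v1 - v4) + lat * spec.ama_true)
    v2 = v4 + 0.55 * L_f * anat_prox

    # femoral joint line: lateral direction at mLDFA from the proximal
    # mechanical axis, measured on the lateral side
    b_f_lat = _dir(_ang(-f) + lat * spec.mldfa_true)
    c_f = v4 + np.array([0.0, 0.25 * gap])
    v3 = c_f + w_f * b_f_lat
    v5 = c_f - w_f * b_f_lat

    # tibial joint line: medial direction at mMPTA from the distal axis
    b_t_med = _dir(_ang(t) + lat * spec.mmpta_true)
    c_t = v7 + np.array([0.0, 0.15 * gap])
    v8 = c_t + w_t * b_t_med
    v6 = c_t - w_t * b_t_med

    coords = np.stack([v1, v2, v3, v4, v5, v6, v7, v8, v9, v10])
    if coords.min() < 2 or coords[:, 0].max() > W - 3 or coords[:, 1].max() > H - 3:
        raise ValueError(
            "phantom geometry exceeds the image frame; "
            "increase image_height/image_width or reduce the deformity"
        )
    return coords


def _capsule(xx, yy, p0, p1, radius, softness):
    """Soft indicator of a thick segment (capsule) on the pixel grid."""
    d = p1 - p0
    len2 = float(d @ d)
    if len2 < 1e-12:
        dist = np.hypot(xx - p0[0], yy - p0[1])
    else:
        tt = np.clip(((xx - p0[0]) * d[0] + (yy - p0[1]) * d[1]) / len2, 0.0, 1.0)
        dist = np.hypot(xx - (p0[0] + tt * d[0]), yy - (p0[1] + tt * d[1]))
    return 1.0 / (1.0 + np.exp((dist - radius) / softness))


def _disc(xx, yy, centre, radius, softness):
    dist = np.hypot(xx - centre[0], yy - centre[1])
    return 1.0 / (1.0 + np.exp((dist - radius) / softness))


def render(spec: PhantomSpec) -> PhantomSample:
    """Render one phantom; the returned landmarks are exact ground truth."""
    coords = _build_landmarks(spec)
    v1, v2, v3, v4, v5, v6, v7, v8, v9, v10 = coords
    H, W = spec.image_height, spec.image_width
    L = 0.88 * H
    soft = max(0.8, 0.004 * L)

    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    img = np.full((H, W), 0.08)

    # soft-tissue silhouette around the whole limb
    img += 0.10 * _capsule(xx, yy, v1, v4, 0.10 * L, 4 * soft)
    img += 0.10 * _capsule(xx, yy, v7, v10, 0.09 * L, 4 * soft)

    # femur: head disc, shaft along the anatomical axis, condylar arcs
    img += 0.45 * _disc(xx, yy, v1, 0.035 * L, soft)
    img += 0.40 * _capsule(xx, yy, v2 + 0.45 * (v2 - v4), v4, 0.022 * L, soft)
    bone_int = 0.95 if spec.has_prosthesis else 0.45
    img += bone_int * _disc(xx, yy, v3, 0.016 * L, soft)
    img += bone_int * _disc(xx, yy, v5, 0.016 * L, soft)
    img += (bone_int - 0.05) * _capsule(xx, yy, v3, v5, 0.012 * L, soft)

    # tibia: plateau line, shaft, ankle
    img += (bone_int - 0.05) * _capsule(xx, yy, v6, v8, 0.012 * L, soft)
    img += bone_int * _disc(xx, yy, v6, 0.013 * L, soft)
    img += bone_int * _disc(xx, yy, v8, 0.013 * L, soft)
    img += 0.40 * _capsule(xx, yy, v7, v10, 0.018 * L, soft)
    img += 0.40 * _disc(xx, yy, v10, 0.025 * L, soft)
    if spec.has_prosthesis:
        # tibial stem of the implant
        img += 0.50 * _capsule(xx, yy, v7, v7 + 0.12 * L * (v10 - v7) / np.hypot(*(v10 - v7)), 0.010 * L, soft)

    rng = np.random.default_rng(spec.seed)
    if spec.capture_degradation == "photo":
        img, coords = _photo_degrade(img, coords, rng)

    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)

    landmarks = LimbLandmarks.from_array(coords, side=spec.side, pixel_spacing_mm=None)
    return PhantomSample(image=img.astype(np.float32), landmarks=landmarks, spec=spec)


def _photo_degrade(img, coords, rng):
    """Handheld-capture emulation: rigid pose jitter, vignette, mild blur.

    The pose jitter is a similarity transform (rotation <= 2 deg plus a
    small translation) applied identically to pixels and landmarks, so all
    relative angles of the ground truth are preserved exactly.
    """
    H, W = img.shape
    angle = float(rng.uniform(-2.0, 2.0))
    shift = rng.uniform(-0.01, 0.01, size=2) * np.array([W, H])
    c, s = math.cos(math.radians(angle)), math.sin(math.radians(angle))
    centre = np.array([W / 2.0, H / 2.0])
    rot = np.array([[c, -s], [s, c]])  # forward rotation in (x, y)

    # scipy's affine_transform maps output -> input in (row, col) order:
    # input = M @ output + offset, with M the inverse rotation
    rot_yx_inv = np.array([[c, -s], [s, c]])
    centre_yx, shift_yx = centre[::-1], shift[::-1]
    offset = centre_yx - rot_yx_inv @ (centre_yx + shift_yx)
    img = ndimage.affine_transform(
        img, rot_yx_inv, offset=offset, order=1, mode="constant", cval=0.08
    )
    coords = (rot @ (coords - centre).T).T + centre + shift

    vy = 1.0 - 0.25 * ((np.arange(H) - H / 2) / (H / 2)) ** 2
    vx = 1.0 - 0.25 * ((np.arange(W) - W / 2) / (W / 2)) ** 2
    img = img * vy[:, None] * vx[None, :]
    img = ndimage.gaussian_filter(img, sigma=0.7)
    return img, coords


def make_dataset(
    n: int,
    params: CohortParams,
    out_dir: str | Path,
    seed: int = 0,
) -> dict:
    """Generate n phantoms; write PNGs, a landmark CSV and a JSON manifest.

    Fully reproducible: re-running with the manifest's seed and parameters
    regenerates byte-identical images.  Returns the manifest dict.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    from .io import write_landmark_csv  # local import to avoid cycle

    rows = []
    entries = []
    for i in range(n):
        spec = sample_spec(params, rng)
        sample = render(spec)
        image_id = f"phantom_{i:05d}"
        png = (np.clip(sample.image, 0, 1) * 255).round().astype(np.uint8)
        iio.imwrite(out_dir / f"{image_id}.png", png)
        rows.append((image_id, sample.landmarks))
        entries.append(
            {
                "image_id": image_id,
                "spec": asdict(spec),
                "sha256": hashlib.sha256(png.tobytes()).hexdigest(),
            }
        )
    write_landmark_csv(rows, out_dir / "landmarks.csv")
    manifest = {"n": n, "seed": seed, "cohort": asdict(params), "samples": entries}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def load_dataset(manifest_path: str | Path) -> list[PhantomSample]:
    """Regenerate the samples recorded in a manifest (no images read)."""
    manifest = json.loads(Path(manifest_path).read_text())
    out = []
    for entry in manifest["samples"]:
        spec = PhantomSpec(**entry["spec"])
        out.append(render(spec))
    return out


def generate_samples(n: int, params: CohortParams, seed: int = 0) -> list[PhantomSample]:
    """In-memory dataset: n rendered phantoms from one seeded stream."""
    rng = np.random.default_rng(seed)
    return [render(sample_spec(params, rng)) for _ in range(n)]
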