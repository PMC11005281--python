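"""Two-branch landmark detection network and its training loop.

The detector follows the high-resolution design used for radiograph
keypoint work: a stem reduces the input once (total stride 2), after which
two parallel streams — a high-resolution stream at 1/2 scale and a
low-resolution stream at 1/4 scale — exchange information through repeated
cross-resolution fusion, so the high-resolution representation is
maintained throughout rather than recovered at the end.  Two heads sit on
top:

* a heatmap head (1x1 conv) predicting one Gaussian response map per
  landmark, by default at the full input resolution (the high stream is
  upsampled and refined once; ``heatmap_stride=2`` keeps the head at 1/2
  scale instead);
* an edge head (global pooling + dense) predicting one normalised
  direction vector per supervised landmark edge.

The edge branch is a training-time geometric consistency constraint only;
inference uses the heatmap branch alone.  Both branches are trained with
squared error, the edge term scaled by ``edge_loss_weight``; the heatmap
term is peak-weighted (``1 + heatmap_weight_beta * target``) because plain
MSE over the overwhelmingly zero background sharpens the Gaussian peaks
too slowly at desk-scale step budgets.

The network is implemented with the NumPy primitives in
:mod:`limbalign._nn`; at the desk scales this package targets (inputs of
order 128x64, widths of order 8-16) it trains in minutes on one CPU.
Training is fully seeded and deterministic.
"""

from __future__ import annotations

import io as _io
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from ._nn import Adam, Conv2D, Dense, GlobalAvgPool, ReLU, Upsample2x
from .geometry import LANDMARK_NAMES, LimbLandmarks, Point2D
from .heatmap_codec import (
    DEFAULT_EDGES,
    CodecConfig,
    decode_heatmaps,
    encode_edges,
    encode_landmarks,
)

__all__ = [
    "DetectorConfig",
    "AugmentConfig",
    "TrainingRecord",
    "ScaleMeta",
    "TwoBranchNet",
    "PredictionResult",
    "preprocess",
    "build_model",
    "train",
    "predict",
    "save_checkpoint",
    "load_checkpoint",
]


# indices swapped when a limb is mirrored: lateral<->medial condyles (v3,
# v5) and plateau points (v6, v8)
_MIRROR_SWAP = ((2, 4), (5, 7))


@dataclass(frozen=True)
class AugmentConfig:
    """Training-time augmentations, each individually toggleable."""

    horizontal_flip: bool = True
    rotation_deg: float = 5.0  # uniform in +/- this; 0 disables
    intensity_scale: float = 0.10  # uniform in 1 +/- this; 0 disables
    noise_sd: float = 0.01  # additive Gaussian; 0 disables


@dataclass(frozen=True)
class DetectorConfig:
    """Detector geometry, optimisation schedule and inference thresholds.

    The reference operating point (640x320 input, 0.79 mm target spacing,
    200 epochs, batch 32, lr 1e-3 stepped to 1e-4 / 1e-5 at epochs 120 and
    170) is the full-scale protocol; :meth:`tiny` returns the desk-scale
    variant used throughout the tests.
    """

    input_height: int = 640
    input_width: int = 320
    target_spacing_mm: float = 0.79
    backbone_width: int = 32
    epochs: int = 200
    batch_size: int = 32
    lr_initial: float = 1e-3
    lr_steps: tuple[tuple[int, float], ...] = ((120, 1e-4), (170, 1e-5))
    edge_loss_weight: float = 0.1
    heatmap_weight_beta: float = 80.0  # peak emphasis in the weighted MSE
    n_stages: int = 4  # cross-resolution fusion stages in the backbone
    seed: int = 0
    detection_threshold: float = 0.3
    heatmap_stride: int = 1  # 1 = full-resolution head, 2 = head at 1/2 scale
    sigma: float = 2.0
    edges: tuple[tuple[int, int], ...] = DEFAULT_EDGES
    augment: AugmentConfig = field(default_factory=AugmentConfig)

    def __post_init__(self) -> None:
        if self.input_height % 4 or self.input_width % 4:
            raise ValueError("input dimensions must be divisible by 4 (backbone stride)")
        epochs_seen = [e for e, _ in self.lr_steps]
        if epochs_seen != sorted(set(epochs_seen)) or any(
            e >= self.epochs for e in epochs_seen
        ):
            raise ValueError("lr step epochs must be strictly increasing and < epochs")
        if self.edge_loss_weight < 0:
            raise ValueError("edge_loss_weight must be >= 0")
        if self.heatmap_stride not in (1, 2):
            raise ValueError("heatmap_stride must be 1 or 2")

    @property
    def heatmap_shape(self) -> tuple[int, int]:
        return (
            self.input_height // self.heatmap_stride,
            self.input_width // self.heatmap_stride,
        )

    def codec(self) -> CodecConfig:
        h, w = self.heatmap_shape
        return CodecConfig(
            heatmap_height=h, heatmap_width=w, sigma=self.sigma, edges=self.edges
        )

    @classmethod
    def tiny(cls, seed: int = 0, **overrides) -> "DetectorConfig":
        """Desk-scale variant: 128x64 input, width 8, 30-epoch schedule."""
        kw = dict(
            input_height=128,
            input_width=64,
            backbone_width=16,
            n_stages=3,
            epochs=30,
            batch_size=2,
            lr_initial=2e-3,
            lr_steps=((24, 5e-4), (28, 1e-4)),
            seed=seed,
        )
        kw.update(overrides)
        return cls(**kw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["lr_steps"] = [list(s) for s in self.lr_steps]
        d["edges"] = [list(e) for e in self.edges]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DetectorConfig":
        d = dict(d)
        d["lr_steps"] = tuple((int(e), float(lr)) for e, lr in d["lr_steps"])
        d["edges"] = tuple((int(a), int(b)) for a, b in d["edges"])
        d["augment"] = AugmentConfig(**d["augment"])
        return cls(**d)


@dataclass
class TrainingRecord:
    epoch: int
    train_loss: float
    validation_mre: float | None = None  # model-frame pixels


@dataclass(frozen=True)
class ScaleMeta:
    """Invertible affine between original and model-frame coordinates.

    ``model = original * scale + (tx, ty)``; ``spacing_mm`` is the physical
    spacing of the model grid, or None when the source spacing is unknown
    (portable-photo mode).
    """

    scale: float
    tx: float
    ty: float
    spacing_mm: float | None
    original_shape: tuple[int, int]

    def to_model(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) * self.scale + np.array([self.tx, self.ty])

    def to_original(self, coords: np.ndarray) -> np.ndarray:
        return (np.asarray(coords, float) - np.array([self.tx, self.ty])) / self.scale


def preprocess(
    image: np.ndarray, spacing_mm: float | None, config: DetectorConfig
) -> tuple[np.ndarray, ScaleMeta]:
    """Resample to the model frame and standardise intensities.

    With a known source spacing the image is rescaled to the target
    spacing (bilinear), so one model pixel spans ``target_spacing_mm``;
    with unknown spacing (portable-photo mode) it is scaled to fit the
    frame.  Either way the aspect ratio is preserved and the result is
    centred in the target frame with zero padding (or symmetric cropping
    when the rescaled image overshoots the frame).  Intensities are
    standardised to zero mean, unit variance per image.  The returned
    :class:`ScaleMeta` maps coordinates both ways exactly.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim == 3:  # RGB -> luminance
        image = image.mean(axis=2)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("expected a non-empty 2D (or RGB) image")
    H, W = image.shape
    th, tw = config.input_height, config.input_width

    if spacing_mm is not None:
        if spacing_mm <= 0:
            raise ValueError("spacing_mm must be positive")
        scale = spacing_mm / config.target_spacing_mm
        out_spacing = config.target_spacing_mm
    else:
        scale = min(th / H, tw / W)
        out_spacing = None

    if image.std() < 1e-12:
        raise ValueError("constant image cannot be standardised")
    nh, nw = max(1, round(H * scale)), max(1, round(W * scale))
    resized = _sk_resize(image, (nh, nw), order=1, anti_aliasing=False, mode="edge")

    frame = np.zeros((th, tw), dtype=float)
    # centre in the frame: positive offset = padding, negative = cropping
    oy, ox = (th - nh) // 2, (tw - nw) // 2
    sy, sx = max(0, -oy), max(0, -ox)
    dy, dx = max(0, oy), max(0, ox)
    cy, cx = min(nh - sy, th - dy), min(nw - sx, tw - dx)
    frame[dy : dy + cy, dx : dx + cx] = resized[sy : sy + cy, sx : sx + cx]

    sd = frame.std()
    if sd < 1e-12:
        raise ValueError("constant image cannot be standardised")
    frame = (frame - frame.mean()) / sd

    meta = ScaleMeta(
        scale=scale, tx=float(ox), ty=float(oy), spacing_mm=out_spacing,
        original_shape=(H, W),
    )
    return frame, meta


class _FuseStage:
    """One cross-resolution exchange between the two streams."""

    def __init__(self, rng, w):
        self.conv_h = Conv2D(rng, w, w, 3)
        self.conv_l = Conv2D(rng, 2 * w, 2 * w, 3)
        self.up_proj = Conv2D(rng, 2 * w, w, 1)
        self.down_proj = Conv2D(rng, w, 2 * w, 3, stride=2)
        self.relu_h, self.relu_l = ReLU(), ReLU()
        self.relu_fh, self.relu_fl = ReLU(), ReLU()
        self.upsample = Upsample2x()

    @property
    def layers(self):
        return (self.conv_h, self.conv_l, self.up_proj, self.down_proj)

    def forward(self, h, l):
        h2 = self.relu_h.forward(self.conv_h.forward(h))
        l2 = self.relu_l.forward(self.conv_l.forward(l))
        hf = self.relu_fh.forward(h2 + self.upsample.forward(self.up_proj.forward(l2)))
        lf = self.relu_fl.forward(l2 + self.down_proj.forward(h2))
        return hf, lf

    def backward(self, dhf, dlf):
        d_sum_h = self.relu_fh.backward(dhf)
        d_sum_l = self.relu_fl.backward(dlf)
        d_h2 = d_sum_h + self.down_proj.backward(d_sum_l)
        d_l2 = d_sum_l + self.up_proj.backward(self.upsample.backward(d_sum_h))
        dh = self.conv_h.backward(self.relu_h.backward(d_h2))
        dl = self.conv_l.backward(self.relu_l.backward(d_l2))
        return dh, dl


class TwoBranchNet:
    """Heatmap + edge-vector network over a two-stream backbone."""

    def __init__(self, config: DetectorConfig, n_landmarks: int = 10):
        self.config = config
        self.n_landmarks = n_landmarks
        self.n_edges = len(config.edges)
        w = config.backbone_width
        rng = np.random.default_rng(config.seed)

        # input = intensity plus two normalised coordinate channels, which
        # let the small backbone resolve positionally defined landmarks
        # (diaphysis centres) that are ambiguous from local appearance
        self.stem = Conv2D(rng, 3, w, 3, stride=2)
        self.stem_relu = ReLU()
        self.low_init = Conv2D(rng, w, 2 * w, 3, stride=2)
        self.low_relu = ReLU()
        self.stages = [_FuseStage(rng, w) for _ in range(config.n_stages)]
        if config.heatmap_stride == 1:
            # full-resolution head: upsample the high stream back to the
            # input grid and refine once before the 1x1 projection
            self.head_up = Upsample2x()
            self.head_conv = Conv2D(rng, w, w, 3)
            self.head_relu = ReLU()
        else:
            self.head_up = self.head_conv = self.head_relu = None
        self.head_hm = Conv2D(rng, w, n_landmarks, 1)
        # zero-init the output heads: predictions start at the all-zero
        # background regardless of seed, which removes init-dependent
        # spurious peaks that can trap individual channels
        self.head_hm.W[...] = 0.0
        self.gap = GlobalAvgPool()
        self.head_edge = Dense(rng, 2 * w, 2 * self.n_edges)
        self.head_edge.W[...] = 0.0

    @property
    def _layers(self):
        layers = [self.stem, self.low_init, self.head_hm, self.head_edge]
        if self.head_conv is not None:
            layers.append(self.head_conv)
        for st in self.stages:
            layers.extend(st.layers)
        return layers

    @property
    def params(self):
        out = []
        for layer in self._layers:
            out.extend(layer.params)
        return out

    def n_parameters(self) -> int:
        return sum(p.size for p, _ in self.params)

    @staticmethod
    def _with_coords(x: np.ndarray) -> np.ndarray:
        N, _, H, W = x.shape
        ys = np.linspace(-1.0, 1.0, H)[None, None, :, None]
        xs = np.linspace(-1.0, 1.0, W)[None, None, None, :]
        coord = np.concatenate(
            [np.broadcast_to(xs, (N, 1, H, W)), np.broadcast_to(ys, (N, 1, H, W))],
            axis=1,
        )
        return np.concatenate([x, coord], axis=1)

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """x: (N, 1, H, W) -> heatmaps (N, K, H/s, W/s), edges (N, E, 2)."""
        h = self.stem_relu.forward(self.stem.forward(self._with_coords(x)))
        l = self.low_relu.forward(self.low_init.forward(h))
        for st in self.stages:
            h, l = st.forward(h, l)
        if self.head_conv is not None:
            h = self.head_relu.forward(self.head_conv.forward(self.head_up.forward(h)))
        hm = self.head_hm.forward(h)
        ev = self.head_edge.forward(self.gap.forward(l))
        return hm, ev.reshape(x.shape[0], self.n_edges, 2)

    def backward(self, d_hm: np.ndarray, d_edge: np.ndarray) -> None:
        dl = self.gap.backward(self.head_edge.backward(d_edge.reshape(d_edge.shape[0], -1)))
        dh = self.head_hm.backward(d_hm)
        if self.head_conv is not None:
            dh = self.head_up.backward(self.head_conv.backward(self.head_relu.backward(dh)))
        for st in reversed(self.stages):
            dh, dl = st.backward(dh, dl)
        dh = dh + self.low_init.backward(self.low_relu.backward(dl))
        self.stem.backward(self.stem_relu.backward(dh))

    def state_arrays(self) -> list[np.ndarray]:
        return [p for p, _ in self.params]


def build_model(config: DetectorConfig, n_landmarks: int = 10) -> TwoBranchNet:
    """Construct the seeded two-branch network for the given config."""
    return TwoBranchNet(config, n_landmarks=n_landmarks)


# ---------------------------------------------------------------------------
# training


def _landmarks_to_model(landmarks: LimbLandmarks, meta: ScaleMeta) -> np.ndarray:
    return meta.to_model(landmarks.as_array())


def _model_to_heatmap(coords: np.ndarray, stride: int) -> np.ndarray:
    """Pixel-centre mapping from the input grid to the heatmap grid."""
    return (np.asarray(coords, float) + 0.5) / stride - 0.5


def _heatmap_to_model(coords: np.ndarray, stride: int) -> np.ndarray:
    return (np.asarray(coords, float) + 0.5) * stride - 0.5


def _augment(img, coords, aug: AugmentConfig, rng):
    """Apply the toggled augmentations to one (image, coords) pair."""
    H, W = img.shape
    if aug.horizontal_flip and rng.random() < 0.5:
        img = img[:, ::-1]
        coords = coords.copy()
        coords[:, 0] = (W - 1) - coords[:, 0]
        for a, b in _MIRROR_SWAP:
            coords[[a, b]] = coords[[b, a]]
    if aug.rotation_deg > 0:
        ang = float(rng.uniform(-aug.rotation_deg, aug.rotation_deg))
        c, s = math.cos(math.radians(ang)), math.sin(math.radians(ang))
        centre = np.array([(W - 1) / 2.0, (H - 1) / 2.0])
        rot_yx_inv = np.array([[c, -s], [s, c]])
        offset = centre[::-1] - rot_yx_inv @ centre[::-1]
        img = ndimage.affine_transform(img, rot_yx_inv, offset=offset, order=1, mode="nearest")
        rot = np.array([[c, -s], [s, c]])
        coords = (rot @ (coords - centre).T).T + centre
    if aug.intensity_scale > 0:
        img = img * float(rng.uniform(1 - aug.intensity_scale, 1 + aug.intensity_scale))
    if aug.noise_sd > 0:
        img = img + rng.normal(0.0, aug.noise_sd, size=img.shape)
    return np.ascontiguousarray(img), coords


def _encode_sample(coords_model, codec, edges, stride):
    hm_coords = _model_to_heatmap(coords_model, stride)
    pts = [Point2D(float(x), float(y)) for x, y in hm_coords]
    stack = encode_landmarks(pts, codec)
    edge_t = encode_edges(pts, edges)
    return stack.values, edge_t.vectors


def train(
    dataset,
    config: DetectorConfig,
    validation=None,
):
    """Train the two-branch network on (image, LimbLandmarks) pairs.

    ``dataset`` (and optional ``validation``) are sequences of
    ``(image, LimbLandmarks)`` tuples or objects with ``.image`` and
    ``.landmarks`` attributes (e.g. phantom samples).  Images are run
    through :func:`preprocess` with their landmarks mapped into the model
    frame.  Returns ``(network, records)``.
    """
    pairs = [_as_pair(s) for s in dataset]
    if not pairs:
        raise ValueError("empty training dataset")
    codec = config.codec()
    rng = np.random.default_rng(config.seed + 1)

    prepped = []
    for img, lms in pairs:
        frame, meta = preprocess(img, lms.pixel_spacing_mm, config)
        prepped.append((frame, _landmarks_to_model(lms, meta)))
    val_prepped = None
    if validation is not None:
        val_prepped = []
        for img, lms in (_as_pair(s) for s in validation):
            frame, meta = preprocess(img, lms.pixel_spacing_mm, config)
            val_prepped.append((frame, _landmarks_to_model(lms, meta)))

    net = build_model(config)
    opt = Adam(net.params, lr=config.lr_initial)
    n = len(prepped)
    records: list[TrainingRecord] = []

    for epoch in range(config.epochs):
        for step_epoch, lr in config.lr_steps:
            if epoch == step_epoch:
                opt.lr = lr
        order = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            imgs, hms, evs = [], [], []
            for i in idx:
                frame, coords = prepped[i]
                frame, coords = _augment(frame, coords, config.augment, rng)
                hm, ev = _encode_sample(coords, codec, config.edges, config.heatmap_stride)
                imgs.append(frame)
                hms.append(hm)
                evs.append(ev)
            x = np.stack(imgs)[:, None]
            hm_t = np.stack(hms)
            ev_t = np.stack(evs)

            hm_p, ev_p = net.forward(x)
            hm_res = hm_p - hm_t
            ev_res = ev_p - ev_t
            # peak-weighted squared error: plain MSE sees mostly background
            # zeros and sharpens the Gaussian peaks far too slowly at this
            # step budget, so pixels are weighted 1 + beta * target
            weight = 1.0 + config.heatmap_weight_beta * hm_t
            loss_hm = float(np.mean(weight * hm_res**2))
            loss_ev = float(np.mean(ev_res**2))
            loss = loss_hm + config.edge_loss_weight * loss_ev
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {n_batches} "
                    f"(samples {idx.tolist()})"
                )
            opt.zero_grad()
            net.backward(
                2.0 * weight * hm_res / hm_res.size,
                config.edge_loss_weight * 2.0 * ev_res / ev_res.size,
            )
            opt.step()
            epoch_loss += loss
            n_batches += 1

        val_mre = None
        if val_prepped is not None:
            val_mre = _validation_mre(net, val_prepped)
        records.append(
            TrainingRecord(epoch=epoch, train_loss=epoch_loss / n_batches,
                           validation_mre=val_mre)
        )
    return net, records


def _as_pair(sample):
    if isinstance(sample, tuple):
        return sample
    return sample.image, sample.landmarks


def _validation_mre(net: TwoBranchNet, prepped) -> float:
    """Mean radial error over a preprocessed validation set, model pixels."""
    errs = []
    for frame, coords in prepped:
        hm_p, _ = net.forward(frame[None, None])
        decoded = decode_heatmaps(hm_p[0])
        for (p, _conf), truth in zip(decoded, coords):
            if p is None:
                continue
            pred = _heatmap_to_model(np.array([p.x, p.y]), net.config.heatmap_stride)
            errs.append(float(np.hypot(*(pred - truth))))
    return float(np.mean(errs)) if errs else float("nan")


# ---------------------------------------------------------------------------
# inference


@dataclass
class PredictionResult:
    """One limb's predicted landmarks in original-image coordinates."""

    landmarks: LimbLandmarks | None
    confidences: np.ndarray  # (10,)
    detected: bool  # False if any landmark confidence < threshold


def _plausible_limb(lm: LimbLandmarks) -> bool:
    """Anatomical sanity of a decoded landmark set.

    The condyles (v3, v5) and plateau points (v6, v8) must straddle their
    knee-centre landmarks horizontally, and the diaphysis centres must lie
    vertically between the joints they connect.  Violations mean the
    detector confused paired channels; such limbs are reported
    not-detected rather than measured.
    """
    if (lm.v3.x - lm.v4.x) * (lm.v5.x - lm.v4.x) >= 0:
        return False
    if (lm.v6.x - lm.v7.x) * (lm.v8.x - lm.v7.x) >= 0:
        return False
    if not (lm.v1.y < lm.v2.y < lm.v4.y):
        return False
    if not (lm.v7.y < lm.v9.y < lm.v10.y):
        return False
    return True


def predict(
    image: np.ndarray,
    spacing_mm: float | None,
    network: TwoBranchNet,
    config: DetectorConfig,
    side: str = "left",
) -> PredictionResult:
    """Detect the ten landmarks of one limb crop.

    Runs preprocess -> forward -> heatmap decoding -> inverse coordinate
    mapping.  The joint counts as not-detected when any landmark's peak
    confidence falls below ``config.detection_threshold``; low confidence
    is reported, never raised.
    """
    frame, meta = preprocess(image, spacing_mm, config)
    hm_p, _ = network.forward(frame[None, None])
    decoded = decode_heatmaps(hm_p[0])

    confidences = np.array([conf for _, conf in decoded])
    detected = bool(np.all(confidences >= config.detection_threshold))
    coords = []
    for p, _conf in decoded:
        if p is None:
            detected = False
            coords.append([np.nan, np.nan])
        else:
            coords.append(
                _heatmap_to_model(np.array([p.x, p.y]), config.heatmap_stride)
            )
    coords = np.asarray(coords, dtype=float)

    landmarks = None
    if not np.any(np.isnan(coords)):
        original = meta.to_original(coords)
        try:
            landmarks = LimbLandmarks.from_array(
                original, side=side, pixel_spacing_mm=spacing_mm
            )
        except Exception:
            detected = False  # decoded points violate limb topology
        else:
            if not _plausible_limb(landmarks):
                detected = False
    return PredictionResult(landmarks=landmarks, confidences=confidences, detected=detected)


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(network: TwoBranchNet, path: str | Path) -> None:
    """Serialise weights plus the embedded config to an .npz file."""
    arrays = {f"p{i}": p for i, (p, _) in enumerate(network.params)}
    buf = _io.BytesIO()
    np.savez(buf, **arrays)
    Path(path).write_bytes(buf.getvalue())
    meta = {"config": network.config.to_dict(), "n_landmarks": network.n_landmarks}
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))


def load_checkpoint(path: str | Path) -> TwoBranchNet:
    meta = json.loads(Path(str(path) + ".json").read_text())
    config = DetectorConfig.from_dict(meta["config"])
    net = build_model(config, n_landmarks=meta["n_landmarks"])
    with np.load(path) as data:
        for i, (p, _) in enumerate(net.params):
            p[...] = data[f"p{i}"]
    return net
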