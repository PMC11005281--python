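"""Preprocessing contract, network shape/determinism, training smoke."""

import dataclasses

import numpy as np
import pytest

from limbalign.detector import (
    AugmentConfig,
    DetectorConfig,
    TwoBranchNet,
    build_model,
    load_checkpoint,
    predict,
    preprocess,
    save_checkpoint,
    train,
)
from limbalign.geometry import measure_limb
from limbalign.heatmap_codec import encode_landmarks
from limbalign.phantom import CohortParams, generate_samples

TINY = DetectorConfig.tiny(seed=0)
SMALL_COHORT = CohortParams(image_height=384, image_width=160, noise_sd=0.02)


class TestPreprocess:
    def test_identity_case_round_trips(self):
        rng = np.random.default_rng(0)
        img = rng.normal(size=(TINY.input_height, TINY.input_width))
        frame, meta = preprocess(img, TINY.target_spacing_mm, TINY)
        assert frame.shape == (TINY.input_height, TINY.input_width)
        pts = np.array([[3.0, 7.0], [50.0, 100.0]])
        assert np.allclose(meta.to_model(pts), pts)
        assert np.allclose(meta.to_original(meta.to_model(pts)), pts)

    def test_known_spacing_rescales_to_target(self):
        # a 2021x2021 source at 0.2 mm/px lands on the 0.79 mm model grid
        rng = np.random.default_rng(1)
        img = rng.normal(size=(2021, 2021))
        cfg = dataclasses.replace(TINY, input_height=640, input_width=640)
        frame, meta = preprocess(img, 0.2, cfg)
        assert meta.spacing_mm == pytest.approx(0.79)
        assert meta.scale == pytest.approx(0.2 / 0.79)

    def test_affine_inverse_exact(self):
        rng = np.random.default_rng(2)
        img = rng.normal(size=(500, 300))
        frame, meta = preprocess(img, None, TINY)
        pts = rng.uniform(0, 300, size=(20, 2))
        assert np.allclose(meta.to_original(meta.to_model(pts)), pts, atol=1e-9)

    def test_standardised_output(self):
        rng = np.random.default_rng(3)
        img = rng.uniform(size=(256, 128))
        frame, _ = preprocess(img, None, TINY)
        assert frame.mean() == pytest.approx(0.0, abs=1e-9)
        assert frame.std() == pytest.approx(1.0, abs=1e-9)

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            preprocess(np.ones((64, 64)), None, TINY)

    def test_rgb_collapsed_to_luminance(self):
        rng = np.random.default_rng(4)
        img = rng.uniform(size=(128, 64, 3))
        frame, _ = preprocess(img, None, TINY)
        assert frame.ndim == 2


class TestNetwork:
    def test_forward_shape_contract(self):
        net = build_model(TINY)
        x = np.zeros((2, 1, TINY.input_height, TINY.input_width))
        hm, ev = net.forward(x)
        assert hm.shape == (2, 10) + TINY.heatmap_shape
        assert ev.shape == (2, len(TINY.edges), 2)

    def test_width_increases_parameter_count(self):
        small = build_model(dataclasses.replace(TINY, backbone_width=8))
        large = build_model(dataclasses.replace(TINY, backbone_width=16))
        assert large.n_parameters() > small.n_parameters()

    def test_forward_deterministic(self):
        net = build_model(TINY)
        x = np.random.default_rng(5).normal(size=(1, 1, TINY.input_height, TINY.input_width))
        hm1, ev1 = net.forward(x)
        hm2, ev2 = net.forward(x)
        assert np.array_equal(hm1, hm2) and np.array_equal(ev1, ev2)

    def test_same_seed_same_init(self):
        a, b = build_model(TINY), build_model(TINY)
        for (pa, _), (pb, _) in zip(a.params, b.params):
            assert np.array_equal(pa, pb)

    def test_invalid_input_size_rejected(self):
        with pytest.raises(ValueError):
            DetectorConfig.tiny(input_height=130)  # not divisible by 4

    def test_lr_steps_validated(self):
        with pytest.raises(ValueError):
            DetectorConfig.tiny(lr_steps=((40, 1e-4),))  # step beyond epochs


class _OracleNet:
    """Emits the exact encoded ground-truth heatmaps for a fixed limb."""

    def __init__(self, config, coords_model):
        from limbalign.detector import _model_to_heatmap
        from limbalign.geometry import Point2D

        self.config = config
        hm_coords = _model_to_heatmap(coords_model, config.heatmap_stride)
        pts = [Point2D(float(x), float(y)) for x, y in hm_coords]
        self._stack = encode_landmarks(pts, config.codec())

    def forward(self, x):
        return self._stack.values[None], np.zeros((1, len(self.config.edges), 2))


class TestPredict:
    def test_oracle_network_recovers_truth(self):
        sample = generate_samples(1, SMALL_COHORT, seed=21)[0]
        frame, meta = preprocess(sample.image, None, TINY)
        coords_model = meta.to_model(sample.landmarks.as_array())
        oracle = _OracleNet(TINY, coords_model)
        result = predict(sample.image, None, oracle, TINY, side=sample.spec.side)
        assert result.detected
        err = np.hypot(
            *(meta.to_model(result.landmarks.as_array()) - coords_model).T
        )
        # decode quantisation: 0.5 heatmap px = 1 model px
        assert err.max() <= 1.0

    def test_low_confidence_is_not_detected(self):
        sample = generate_samples(1, SMALL_COHORT, seed=22)[0]
        frame, meta = preprocess(sample.image, None, TINY)
        coords_model = meta.to_model(sample.landmarks.as_array())
        oracle = _OracleNet(TINY, coords_model)
        weak = dataclasses.replace(TINY, detection_threshold=1.5)
        result = predict(sample.image, None, oracle, weak, side=sample.spec.side)
        assert not result.detected


@pytest.fixture(scope="module")
def short_training():
    """One short shared run: 24 phantoms, 6 epochs, augmentation off."""
    samples = generate_samples(24, SMALL_COHORT, seed=31)
    cfg = DetectorConfig.tiny(
        seed=2, epochs=6, lr_steps=((4, 5e-4),),
        augment=AugmentConfig(horizontal_flip=False, rotation_deg=0.0,
                              intensity_scale=0.0, noise_sd=0.0),
    )
    net, records = train(samples, cfg, validation=samples[:4])
    return samples, cfg, net, records


class TestTraining:
    def test_loss_decreases(self, short_training):
        _, _, _, records = short_training
        assert records[-1].train_loss < records[0].train_loss / 2

    def test_records_ordered_and_finite(self, short_training):
        _, _, _, records = short_training
        assert [r.epoch for r in records] == list(range(6))
        assert all(np.isfinite(r.train_loss) for r in records)
        assert all(r.validation_mre is not None for r in records)

    def test_same_seed_identical_loss_curve(self, short_training):
        samples, cfg, _, records = short_training
        _, records2 = train(samples, cfg)
        assert [r.train_loss for r in records] == [r.train_loss for r in records2]

    def test_edge_weight_zero_still_trains(self):
        samples = generate_samples(8, SMALL_COHORT, seed=33)
        cfg = DetectorConfig.tiny(
            seed=3, epochs=5, lr_steps=(), edge_loss_weight=0.0,
            augment=AugmentConfig(horizontal_flip=False, rotation_deg=0.0,
                                  intensity_scale=0.0, noise_sd=0.0),
        )
        _, records = train(samples, cfg)
        assert records[-1].train_loss < records[0].train_loss

    def test_checkpoint_roundtrip(self, short_training, tmp_path):
        samples, cfg, net, _ = short_training
        path = tmp_path / "model.npz"
        save_checkpoint(net, path)
        loaded = load_checkpoint(path)
        x = np.random.default_rng(6).normal(size=(1, 1, cfg.input_height, cfg.input_width))
        hm1, _ = net.forward(x)
        hm2, _ = loaded.forward(x)
        assert np.array_equal(hm1, hm2)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train([], TINY)
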