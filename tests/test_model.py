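import numpy as np
import pytest

from dermoseg.model import ResUNet, build_resunet, load_model, predict_mask, save_model

# (name, height, width, channels) for every row of the layer tables at
# multiplier 1 and a 256x256 input
ENCODER_ROWS = [
    ("conv1", 128, 128, 64),
    ("pool", 64, 64, 64),
    ("conv2", 64, 64, 256),
    ("conv3", 32, 32, 512),
    ("conv4", 16, 16, 1024),
    ("conv5", 8, 8, 2048),
]
DECODER_ROWS = [
    ("U1", 16, 16, 2048),
    ("D1", 16, 16, 256),
    ("D2", 16, 16, 256),
    ("U2", 32, 32, 256),
    ("D3", 32, 32, 128),
    ("D4", 32, 32, 128),
    ("U3", 64, 64, 128),
    ("D5", 64, 64, 64),
    ("D6", 64, 64, 64),
    ("U4", 128, 128, 64),
    ("D7", 128, 128, 32),
    ("D8", 128, 128, 32),
    ("U5", 256, 256, 32),
    ("D9", 256, 256, 16),
    ("D10", 256, 256, 16),
    ("output", 256, 256, 1),
]


@pytest.fixture(scope="module")
def tiny_model():
    return build_resunet(width_multiplier=0.0625, seed=3)


class TestArchitecture:
    def test_full_width_shape_walk_matches_layer_tables(self):
        model = build_resunet(width_multiplier=1.0, seed=0)
        walk = {r.name: (r.height, r.width, r.channels) for r in model.shape_walk()}
        for name, h, w, c in ENCODER_ROWS + DECODER_ROWS:
            assert walk[name] == (h, w, c), f"{name}: {walk[name]} != {(h, w, c)}"

    def test_quarter_width_scales_channels_only(self):
        model = build_resunet(width_multiplier=0.25, seed=0)
        walk = {r.name: (r.height, r.width, r.channels) for r in model.shape_walk()}
        for name, h, w, c in ENCODER_ROWS + DECODER_ROWS:
            expected_c = 1 if name == "output" else max(1, round(c * 0.25))
            assert walk[name] == (h, w, expected_c)

    def test_decoder_has_ten_3x3_convs(self, tiny_model):
        convs = [m.conv for m in tiny_model.decoder.convs]
        assert len(convs) == 10
        assert all(c.kernel_size == 3 for c in convs)
        assert len(tiny_model.decoder.ups) == 5
        assert all(u.kernel_size == 2 and u.stride == 2 for u in tiny_model.decoder.ups)

    def test_rejects_nonpositive_multiplier(self):
        with pytest.raises(ValueError):
            ResUNet(width_multiplier=0.0)
        with pytest.raises(ValueError):
            ResUNet(width_multiplier=-1)


class TestForward:
    def test_output_in_unit_interval(self, tiny_model, rng):
        x = rng.normal(size=(2, 3, 256, 256)).astype(np.float32)
        p = tiny_model.forward(x)
        assert p.shape == (2, 256, 256)
        assert p.min() >= 0.0 and p.max() <= 1.0

    def test_inference_deterministic(self, tiny_model, rng):
        x = rng.normal(size=(1, 3, 256, 256)).astype(np.float32)
        assert np.array_equal(tiny_model.forward(x), tiny_model.forward(x))

    def test_batching_preserves_order_and_content(self, tiny_model, rng):
        x = rng.normal(size=(3, 3, 256, 256)).astype(np.float32)
        batched = tiny_model.forward(x)
        singles = [tiny_model.forward(x[i : i + 1])[0] for i in range(3)]
        for i in range(3):
            assert np.allclose(batched[i], singles[i], atol=1e-5)

    def test_rejects_wrong_resolution(self, tiny_model, rng):
        with pytest.raises(ValueError):
            tiny_model.forward(rng.normal(size=(1, 3, 128, 128)).astype(np.float32))
        with pytest.raises(ValueError):
            tiny_model.forward(rng.normal(size=(1, 1, 256, 256)).astype(np.float32))


class _ConstantModel:
    def __init__(self, value_map):
        self.value_map = value_map

    def forward(self, batch):
        return self.value_map[None]


class TestPredictMask:
    def test_high_probability_gives_all_ones(self, rng):
        img = rng.integers(0, 256, size=(256, 256, 3), dtype=np.uint8)
        model = _ConstantModel(np.full((256, 256), 0.9))
        assert predict_mask(model, img).all()

    def test_threshold_tie_is_background(self, rng):
        img = rng.integers(0, 256, size=(256, 256, 3), dtype=np.uint8)
        model = _ConstantModel(np.full((256, 256), 0.5))
        assert predict_mask(model, img, threshold=0.5).sum() == 0

    def test_foreground_count_matches_exceedances(self, rng):
        img = rng.integers(0, 256, size=(256, 256, 3), dtype=np.uint8)
        pmap = rng.random((256, 256))
        model = _ConstantModel(pmap)
        mask = predict_mask(model, img)
        assert mask.sum() == (pmap > 0.5).sum()

    def test_restores_original_resolution(self, rng):
        img = rng.integers(0, 256, size=(300, 400, 3), dtype=np.uint8)
        model = _ConstantModel((np.mgrid[0:256, 0:256][0] > 128).astype(float))
        mask = predict_mask(model, img)
        assert mask.shape == (300, 400)
        assert set(np.unique(mask)) <= {0, 1}


class TestWeights:
    def test_pretrained_encoder_roundtrip(self):
        donor = build_resunet(width_multiplier=0.0625, seed=42)
        weights = {f"encoder.{k}": v.data for k, v in donor.encoder.named_parameters()}
        model = build_resunet(width_multiplier=0.0625, seed=7, pretrained_encoder=weights)
        for (_, a), (_, b) in zip(
            model.encoder.named_parameters(), donor.encoder.named_parameters()
        ):
            assert np.array_equal(a.data, b.data)

    def test_pretrained_shape_mismatch_rejected(self):
        donor = build_resunet(width_multiplier=0.125, seed=0)
        weights = {f"encoder.{k}": v.data for k, v in donor.encoder.named_parameters()}
        with pytest.raises(ValueError):
            build_resunet(width_multiplier=0.0625, pretrained_encoder=weights)

    def test_unknown_parameter_rejected(self):
        with pytest.raises(KeyError):
            build_resunet(
                width_multiplier=0.0625, pretrained_encoder={"encoder.nope": np.zeros(3)}
            )

    def test_save_load_roundtrip(self, tiny_model, tmp_path, rng):
        path = tmp_path / "model.npz"
        save_model(tiny_model, path)
        assert (tmp_path / "model.npz.json").exists()
        loaded = load_model(path)
        x = rng.normal(size=(1, 3, 256, 256)).astype(np.float32)
        assert np.array_equal(tiny_model.forward(x), loaded.forward(x))

    def test_parameter_count_scales_with_width(self):
        small = build_resunet(width_multiplier=0.0625, seed=0).parameter_count()
        large = build_resunet(width_multiplier=0.125, seed=0).parameter_count()
        assert small > 0
        assert 2.5 < large / small < 4.5  # ~quadratic in width
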