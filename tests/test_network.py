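"""Architecture contracts: shapes, SE scaling, pooling/upsampling, checkpoints."""

import numpy as np
import pytest

from fazseg import autodiff as ad
from fazseg.network import (
    ConvBNReLU,
    NetworkConfig,
    PoolingBlock,
    SEBlock,
    SegmentationNetwork,
    UpsamplingBlock,
    load_checkpoint,
    save_checkpoint,
    shape_trace,
)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def _fmap(rng, n, c, h, w):
    t = ad.Tensor(rng.standard_normal((n, c, h, w)).astype(np.float32))
    t.requires_grad = True
    return t


class TestShapeTrace:
    def test_study_scale_bottleneck_is_22(self):
        trace = {name: (h, w, d) for name, h, w, d in shape_trace(NetworkConfig())}
        assert trace["P5"][:2] == (22, 22)
        assert trace["U5"][:2] == (704, 704)
        assert trace["R1"] == (704, 704, 1)

    def test_encoder_halving_sequence(self):
        sizes = [h for name, h, w, d in shape_trace(NetworkConfig()) if name.startswith("P")]
        assert sizes == [352, 176, 88, 44, 22]

    def test_scaled_down_bottleneck(self):
        trace = {name: h for name, h, w, d in shape_trace(NetworkConfig.scaled_down())}
        assert trace["P5"] == 4
        assert trace["U5"] == 128

    def test_decoder_mirrors_encoder_depths(self):
        cfg = NetworkConfig.scaled_down()
        trace = dict((name, d) for name, h, w, d in shape_trace(cfg))
        assert trace["U5"] == cfg.channel_schedule[0]
        assert trace["U1"] == cfg.channel_schedule[4]

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            NetworkConfig(input_size=100)  # not divisible by 32
        with pytest.raises(ValueError):
            NetworkConfig(channel_schedule=(8, 16))
        with pytest.raises(ValueError):
            NetworkConfig(kernel_size=4)


class TestBlocks:
    def test_conv_bn_relu_shape_and_nonnegativity(self, rng):
        block = ConvBNReLU(3, 5, 3, rng)
        out = block(_fmap(rng, 2, 3, 8, 8))
        assert out.shape == (2, 5, 8, 8)
        assert (out.data >= 0).all()

    def test_se_weights_in_unit_interval_and_pure_scaling(self, rng):
        se = SEBlock(8, 4, rng)
        x = _fmap(rng, 2, 8, 6, 6)
        s = se.channel_weights(x).data
        assert ((s > 0) & (s < 1)).all()
        out = se(x).data
        # each channel is multiplied by its scalar weight
        ratio = out / x.data
        for n in range(2):
            for c in range(8):
                vals = ratio[n, c][np.abs(x.data[n, c]) > 1e-3]
                np.testing.assert_allclose(vals, s[n, c], rtol=1e-4)

    def test_se_zero_weights_halve_the_input(self, rng):
        se = SEBlock(8, 4, rng)
        for p in se.parameters():
            p.data[:] = 0.0
        x = _fmap(rng, 1, 8, 4, 4)
        np.testing.assert_allclose(se(x).data, x.data / 2, rtol=1e-6)

    def test_se_reduction_exceeding_channels_rejected(self, rng):
        with pytest.raises(ValueError):
            SEBlock(2, 4, rng)

    def test_pooling_block_halves_and_exposes_skip(self, rng):
        block = PoolingBlock(3, 6, 3, 2, rng)
        pooled, skip = block(_fmap(rng, 1, 3, 8, 8))
        assert skip.shape == (1, 6, 8, 8)
        assert pooled.shape == (1, 6, 4, 4)
        # pooled values are window maxima of the skip
        w = skip.data.reshape(1, 6, 4, 2, 4, 2)
        np.testing.assert_allclose(pooled.data, w.max(axis=(3, 5)), rtol=1e-6)

    def test_pooling_block_rejects_odd_dims(self, rng):
        block = PoolingBlock(3, 6, 3, 2, rng)
        with pytest.raises(ValueError):
            block(_fmap(rng, 1, 3, 7, 7))

    def test_upsampling_block_restores_skip_size(self, rng):
        block = UpsamplingBlock(6, 6, 4, 3, 2, rng)
        out = block(_fmap(rng, 1, 6, 4, 4), _fmap(rng, 1, 6, 8, 8))
        assert out.shape == (1, 4, 8, 8)

    def test_upsampling_block_rejects_mismatched_skip(self, rng):
        block = UpsamplingBlock(6, 6, 4, 3, 2, rng)
        with pytest.raises(ValueError):
            block(_fmap(rng, 1, 6, 4, 4), _fmap(rng, 1, 6, 6, 6))


class TestFullNetwork:
    def test_output_shape_and_probability_range(self):
        cfg = NetworkConfig(input_size=64, channel_schedule=(4, 4, 8, 8, 8, 8), se_reduction=2)
        net = SegmentationNetwork(cfg, seed=1)
        x = np.random.default_rng(2).random((1, 1, 64, 64), dtype=np.float32)
        out = net.forward(x).data
        assert out.shape == (1, 1, 64, 64)
        assert ((out > 0) & (out < 1)).all()

    def test_wrong_input_size_rejected(self):
        cfg = NetworkConfig(input_size=64, channel_schedule=(4, 4, 8, 8, 8, 8), se_reduction=2)
        net = SegmentationNetwork(cfg, seed=1)
        with pytest.raises(ValueError):
            net.forward(np.zeros((1, 1, 32, 32), dtype=np.float32))

    def test_seeded_initialization_reproducible(self):
        cfg = NetworkConfig(input_size=64, channel_schedule=(4, 4, 8, 8, 8, 8), se_reduction=2)
        a = SegmentationNetwork(cfg, seed=7)
        b = SegmentationNetwork(cfg, seed=7)
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa.data, pb.data)

    def test_checkpoint_roundtrip(self, tmp_path):
        cfg = NetworkConfig(input_size=64, channel_schedule=(4, 4, 8, 8, 8, 8), se_reduction=2)
        net = SegmentationNetwork(cfg, seed=3)
        net.train(False)
        x = np.random.default_rng(4).random((64, 64), dtype=np.float32)
        before = net.predict_proba(x[None])
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, net, meta={"note": "test"})
        restored, meta = load_checkpoint(path)
        assert meta == {"note": "test"}
        np.testing.assert_allclose(restored.predict_proba(x[None]), before, rtol=1e-6)

    def test_single_sample_overfit_smoke(self):
        """A reduced network can memorize one sample within 200 steps."""
        from fazseg.train import Adam

        rng = np.random.default_rng(5)
        cfg = NetworkConfig(input_size=64, channel_schedule=(4, 8, 8, 8, 8, 8), se_reduction=2)
        net = SegmentationNetwork(cfg, seed=6)
        yy, xx = np.mgrid[0:64, 0:64]
        target = (((yy - 32) ** 2 + (xx - 30) ** 2) < 144).astype(np.float32)[None, None]
        img = (1.0 - target + 0.1 * rng.random((1, 1, 64, 64))).astype(np.float32)
        opt = Adam(net.parameters(), lr=5e-3)
        dice = 0.0
        for step in range(200):
            loss = ad.bce_with_logits(net.forward_logits(img), target)
            opt.zero_grad()
            loss.backward()
            opt.step()
            pred = net.forward(img).data > 0.5
            inter = (pred & (target > 0.5)).sum()
            dice = 2 * inter / (pred.sum() + target.sum())
            if dice > 0.99:
                break
        assert dice > 0.99
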