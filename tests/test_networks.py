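import numpy as np
import pytest

import sparsect.nn as nn
from sparsect.networks import (LayerSpec, Network, NetworkSpec,
                               build_3lssnet, build_resunet, forward)


class TestBuilders:
    def test_3lssnet_variants_layer_shapes(self):
        tc = build_3lssnet("table-consistent")
        assert [(l.kernel, l.in_channels, l.out_channels)
                for l in tc.layers] == [(9, 1, 128), (3, 128, 64), (5, 64, 1)]
        at = build_3lssnet("as-text")
        assert [(l.kernel, l.in_channels, l.out_channels)
                for l in at.layers] == [(9, 1, 128), (5, 128, 128), (3, 128, 1)]
        for spec in (tc, at):
            assert not spec.residual_mode
            assert spec.layers[-1].activation == "linear"
            assert not spec.layers[-1].normalization
            assert all(l.normalization and l.activation == "relu"
                       for l in spec.layers[:-1])

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            build_3lssnet("wide")

    def test_resunet_channel_ladder_doubles(self):
        spec = build_resunet()
        enc_convs = [l for l, _ in spec.flat_layers() if l.kind == "conv"]
        channels = []
        for l in enc_convs:
            if l.out_channels not in channels:
                channels.append(l.out_channels)
        assert channels[:5] == [64, 128, 256, 512, 1024]
        assert spec.residual_mode

    def test_resunet_encoder_decoder_mirror(self):
        spec = build_resunet(c0=8, L=3, n=2)
        layers = [l for l, _ in spec.flat_layers()]
        n_pool = sum(1 for l in layers if l.kind == "pool")
        n_up = sum(1 for l in layers if l.kind == "upsample")
        assert n_pool == n_up == 3
        scales = [s for l, s in spec.flat_layers() if l.kind == "conv"]
        assert min(scales) == 1 / 2 ** 3 and scales[-1] == 1.0

    def test_resunet_final_layer_tanh_single_channel(self):
        layers = [l for l, _ in build_resunet(c0=8).flat_layers()]
        last = layers[-1]
        assert last.kind == "conv" and last.out_channels == 1
        assert last.activation == "tanh" and not last.normalization


class TestForward:
    def test_output_shape_matches_input(self):
        net = Network(build_3lssnet(), seed=0)
        y = np.random.default_rng(0).random((40, 40)).astype(np.float32)
        assert net.predict(y).shape == (40, 40)
        ru = Network(build_resunet(c0=4, L=2), seed=0)
        assert ru.predict(y[:32, :32]).shape == (32, 32)

    def test_residual_zero_subnet_is_identity(self):
        net = Network(build_resunet(c0=4, L=2), seed=1)
        final = net._final_conv()
        final.weight.value[...] = 0.0
        final.bias.value[...] = 0.0
        y = np.random.default_rng(1).random((32, 32)).astype(np.float32)
        np.testing.assert_array_equal(net.predict(y), y)

    def test_residual_bounded_by_tanh(self):
        net = Network(build_resunet(c0=4, L=2), seed=2)
        head = net._final_conv()    # exaggerate the residual head
        head.weight.value[...] = 1000.0
        head.bias.value[...] = 500.0
        y = np.random.default_rng(2).random((32, 32)).astype(np.float32)
        resid = np.abs(net.predict(y) - y)
        assert np.isfinite(resid).all()
        assert resid.max() <= 1.0 + 1e-6

    def test_divisibility_error_names_constraint(self):
        net = Network(build_resunet(c0=4, L=3), seed=0)
        with pytest.raises(ValueError, match="2\\^L"):
            net.predict(np.zeros((36, 36), np.float32))

    def test_zero_input_zero_biases_gives_zero_output(self):
        net = Network(build_3lssnet(), seed=3)
        out = net.predict(np.zeros((24, 24), np.float32))
        np.testing.assert_allclose(out, 0.0, atol=1e-7)

    def test_forward_entry_point_uses_spec_params(self):
        spec = build_3lssnet()
        y = np.random.default_rng(3).random((24, 24)).astype(np.float32)
        a = forward(spec, y, seed=5)
        b = forward(spec, y, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_translation_consistency_on_constant_background(self):
        # stride-aligned shift of a feature in a constant field shifts the
        # output correspondingly (checks the padding convention)
        net = Network(build_resunet(c0=4, L=2), seed=4)
        shift = 4                   # multiple of 2^L
        base = np.zeros((48, 48), np.float32)
        base[20:24, 20:24] = 1.0
        out1 = net.predict(base)
        out2 = net.predict(np.roll(base, shift, axis=1))
        np.testing.assert_allclose(out2[:, 12 + shift:36 + shift],
                                   out1[:, 12:36], atol=1e-4)


class TestSerialization:
    def test_roundtrip_architecture_and_weights(self, tmp_path):
        spec = build_resunet(c0=4, L=2)
        net = Network(spec, seed=7)
        net.sync_spec()
        y = np.random.default_rng(7).random((32, 32)).astype(np.float32)
        before = net.predict(y)
        path = tmp_path / "ckpt.npz"
        spec.save(path)
        loaded = NetworkSpec.load(path)
        assert loaded.to_json() == spec.to_json()
        after = Network(loaded).predict(y)
        np.testing.assert_array_equal(before, after)

    def test_spec_json_roundtrip(self):
        spec = build_3lssnet("as-text")
        again = NetworkSpec.from_json(spec.to_json())
        assert again == NetworkSpec.from_json(again.to_json())
        assert [l.kernel for l in again.layers] == [9, 5, 3]


class TestGradients:
    def test_backward_matches_finite_differences(self):
        """Smooth-activation twin of a conv/BN block: finite differences
        validate every weight gradient through the batch-norm coupling."""
        spec = NetworkSpec("tiny", "sequential", [
            LayerSpec("conv", 3, 1, 1, 4, True, "tanh"),
            LayerSpec("conv", 3, 1, 4, 1, False, "linear")])
        net = Network(spec, seed=1)
        x = np.random.default_rng(2).random((2, 8, 8, 1)).astype(np.float32)
        gt = np.random.default_rng(3).random((2, 8, 8, 1)).astype(np.float32)

        def loss_value():
            out = net.forward_batch(x, training=True)
            return float(np.sum((out.astype(np.float64) - gt) ** 2))

        for p in net.params():
            p.grad[...] = 0
        out = net.forward_batch(x, training=True)
        net.backward_batch((2.0 * (out - gt)).astype(np.float32))
        rng = np.random.default_rng(0)
        for p in net.params():
            if p.name.endswith(".bias") and p is not net.params()[-1]:
                continue            # cancelled by the following batch-norm
            idx = tuple(rng.integers(0, s) for s in p.value.shape)
            eps = 5e-3
            old = p.value[idx]
            p.value[idx] = old + eps
            lp = loss_value()
            p.value[idx] = old - eps
            lm = loss_value()
            p.value[idx] = old
            numeric = (lp - lm) / (2 * eps)
            assert numeric == pytest.approx(float(p.grad[idx]),
                                            rel=0.05, abs=2e-2), p.name
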