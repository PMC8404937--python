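import numpy as np
import pytest

from sparsect.fbp import FilterSpec
from sparsect.networks import build_3lssnet, build_resunet
from sparsect.phantoms import PhantomSpec, generate_dataset
from sparsect.projector import make_geometry
from sparsect.training import (PairedDataset, TrainConfig, build_pairs,
                               desk_train_config, loss, lr_schedule,
                               reference_train_config, train)
from .conftest import make_disk


class TestLoss:
    def test_identical_images_zero(self):
        img = np.random.default_rng(0).random((8, 8))
        assert loss(img, img) == 0.0

    def test_sum_of_squares(self):
        a = np.zeros((4, 4))
        b = np.zeros((4, 4))
        b[0, 0], b[1, 1] = 3.0, 4.0
        assert loss(a, b) == 25.0

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        a, b = rng.random((6, 6)), rng.random((6, 6))
        assert loss(a, b) == pytest.approx(loss(b, a))

    def test_dim_mismatch_rejected(self):
        with pytest.raises(ValueError):
            loss(np.zeros((4, 4)), np.zeros((4, 5)))


class TestLRSchedule:
    def test_endpoints(self):
        cfg = TrainConfig()
        assert lr_schedule(0, 100, cfg) == pytest.approx(1e-2)
        assert lr_schedule(100, 100, cfg) == pytest.approx(1e-5)

    def test_monotone_nonincreasing(self):
        cfg = TrainConfig(lr_power=2.0)
        vals = [lr_schedule(t, 50, cfg) for t in range(51)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_zero_total_steps_returns_start(self):
        assert lr_schedule(0, 0, TrainConfig()) == 1e-2

    def test_presets(self):
        p = reference_train_config("3l-ssnet")
        assert p.optimizer == "adam" and p.epochs == 50
        r = reference_train_config("resunet")
        assert r.optimizer == "sgd-nesterov" and r.momentum == 0.99
        assert r.grad_clip == 5.0 and r.batch_size == 8
        d = desk_train_config("resunet")
        assert d.epochs == 15 and d.optimizer == "sgd-nesterov"


class TestBuildPairs:
    def test_noiseless_dense_parallel_pair_near_exact(self):
        disk = make_disk(128, 40.0)
        geom = make_geometry("custom", 128, beam="parallel", n_views=180,
                             angle_end=180.0)
        ds = build_pairs([disk], geom, 0.0, FilterSpec(), seed=0)
        re = np.linalg.norm(ds.y[0] - ds.gt[0]) / np.linalg.norm(ds.gt[0])
        assert re < 0.05

    def test_pair_count_and_determinism(self):
        gts = generate_dataset(3, PhantomSpec(size=32), seed=2)
        geom = make_geometry("custom", 32, n_views=30)
        a = build_pairs(gts, geom, 1e-2, seed=5)
        b = build_pairs(gts, geom, 1e-2, seed=5)
        assert a.n_pairs == 3
        np.testing.assert_array_equal(a.y, b.y)
        assert a.seeds == b.seeds

    def test_size_mismatch_rejected(self):
        geom = make_geometry("custom", 32, n_views=10)
        with pytest.raises(ValueError):
            build_pairs([np.zeros((32, 32)), np.zeros((16, 16))], geom, 0.0)

    def test_empty_input_rejected(self):
        geom = make_geometry("custom", 32, n_views=10)
        with pytest.raises(ValueError):
            build_pairs([], geom, 0.0)

    def test_concatenate_pools_pairs(self):
        gts = generate_dataset(2, PhantomSpec(size=32), seed=2)
        g1 = make_geometry("custom", 32, n_views=30)
        a = build_pairs(gts, g1, 1e-2, seed=5)
        both = PairedDataset.concatenate([a, a])
        assert both.n_pairs == 4 and both.geometry_tag == "mixed"


def _tiny_pairs(n=12, size=24, seed=0):
    rng = np.random.default_rng(seed)
    import scipy.ndimage as ndi
    gt = np.stack([ndi.gaussian_filter(rng.random((size, size)), 1.5)
                   for _ in range(n)]).astype(np.float32)
    y = gt + rng.normal(0, 0.08, gt.shape).astype(np.float32)
    return PairedDataset(y=y.astype(np.float32), gt=gt,
                         geometry_tag="custom", noise_level=0.08)


class TestTrain:
    def test_3lssnet_loss_decreases(self):
        cfg = TrainConfig(optimizer="adam", epochs=6, seed=0)
        _, hist = train(build_3lssnet(), _tiny_pairs(), cfg)
        assert hist[-1] < hist[0]

    def test_resunet_identity_task_shrinks_residual(self):
        # y == gt: the optimum of the residual model is R == 0.  Start from
        # a deliberately loud residual head so there is something to shrink.
        from sparsect.networks import Network
        from sparsect.training import recalibrate_bn
        ds = _tiny_pairs(n=8, size=32)
        ds = PairedDataset(y=ds.gt.copy(), gt=ds.gt,
                           geometry_tag="custom", noise_level=0.0)
        spec = build_resunet(c0=4, L=2)
        seed = 1
        loud = Network(spec, seed=seed)
        loud._final_conv().weight.value[...] = 0.02
        loud.sync_spec()
        recalibrate_bn(loud, ds)
        resid_before = float(np.mean(np.abs(loud.predict(ds.y[0]) - ds.y[0])))
        cfg = TrainConfig(optimizer="sgd-nesterov", momentum=0.9,
                          lr_start=1e-3, epochs=8, seed=seed)
        net, hist = train(spec, ds, cfg)
        resid_after = float(np.mean(np.abs(net.predict(ds.y[0]) - ds.y[0])))
        assert resid_after < resid_before
        assert hist[-1] < hist[0]

    def test_fixed_seed_identical_history(self):
        cfg = TrainConfig(optimizer="adam", epochs=3, seed=3)
        _, h1 = train(build_3lssnet(), _tiny_pairs(), cfg)
        _, h2 = train(build_3lssnet(), _tiny_pairs(), cfg)
        assert h1 == h2

    def test_empty_dataset_rejected(self):
        ds = _tiny_pairs(n=1)
        empty = PairedDataset(y=ds.y[:0], gt=ds.gt[:0],
                              geometry_tag="custom", noise_level=0.0)
        with pytest.raises(ValueError):
            train(build_3lssnet(), empty, TrainConfig())

    def test_divergence_aborts_with_diagnostic(self):
        # the direct map has an unbounded linear output layer, so an absurd
        # step size overflows float32 within a few updates
        cfg = TrainConfig(optimizer="sgd-nesterov", epochs=6, seed=0,
                          lr_start=1e8, lr_end=1e8, grad_clip=1e30)
        with pytest.raises(RuntimeError, match="diverged"):
            train(build_3lssnet(), _tiny_pairs(n=8), cfg)

    def test_trained_weights_sync_to_spec(self):
        spec = build_3lssnet()
        cfg = TrainConfig(optimizer="adam", epochs=1, seed=0)
        net, _ = train(spec, _tiny_pairs(n=4), cfg)
        assert net.trained and spec.params
        key = next(iter(spec.params))
        assert np.array_equal(spec.params[key],
                              {p.name: p.value for p in net.params()}[key])
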