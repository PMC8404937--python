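import math

import numpy as np
import pytest
import scipy.ndimage as ndi
from hypothesis import given, settings
from hypothesis import strategies as st

from sparsect.metrics import (evaluate, fsim, psnr, relative_error, ssim)


@pytest.fixture(scope="module")
def textured():
    rng = np.random.default_rng(0)
    g = ndi.gaussian_filter(rng.random((96, 96)), 2.0)
    return (g - g.min()) / (g.max() - g.min())


class TestRelativeError:
    def test_identity_zero(self, textured):
        assert relative_error(textured, textured) == 0.0

    def test_zero_estimate_gives_one(self, textured):
        assert relative_error(np.zeros_like(textured), textured) == pytest.approx(1.0)

    def test_doubled_image_gives_one(self, textured):
        assert relative_error(2 * textured, textured) == pytest.approx(1.0)

    def test_squared_variant(self, textured):
        r = relative_error(2 * textured, textured)
        assert relative_error(2 * textured, textured, squared=True) == \
            pytest.approx(r * r)

    def test_scale_invariance(self, textured):
        x = textured + 0.1
        for c in (0.5, 3.0, 17.0):
            assert relative_error(c * x, c * textured) == \
                pytest.approx(relative_error(x, textured))

    def test_zero_gt_rejected(self):
        with pytest.raises(ValueError):
            relative_error(np.ones((4, 4)), np.zeros((4, 4)))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            relative_error(np.ones((4, 4)), np.ones((4, 5)))


class TestPSNR:
    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 10_000))
    def test_variant_identity_10log10n(self, seed):
        rng = np.random.default_rng(seed)
        gt = rng.random((12, 12)) + 0.1
        x = gt + rng.normal(0, 0.05, gt.shape)
        pp, ps = psnr(x, gt)
        assert pp - ps == pytest.approx(10 * math.log10(gt.size), abs=1e-9)

    def test_doubling_error_costs_6dB(self, textured):
        e = np.random.default_rng(1).normal(0, 0.05, textured.shape)
        p1 = psnr(textured + e, textured)
        p2 = psnr(textured + 2 * e, textured)
        drop = 20 * math.log10(2)
        assert p1[0] - p2[0] == pytest.approx(drop, abs=1e-9)
        assert p1[1] - p2[1] == pytest.approx(drop, abs=1e-9)

    def test_printed_formula_anchor(self):
        gt = np.array([[1.0, 0.5], [0.25, 0.0]])
        x = gt + np.array([[2.0, 0.0], [0.0, 2 * math.sqrt(3)]])
        # n * max(gt) / ||x-gt|| = 4 * 1 / 4 = 1 -> 0 dB
        assert psnr(x, gt)[0] == pytest.approx(0.0, abs=1e-12)

    def test_identical_images_infinite(self, textured):
        assert psnr(textured, textured) == (math.inf, math.inf)


class TestSSIM:
    def test_identity(self, textured):
        assert ssim(textured, textured) == pytest.approx(1.0)

    def test_constant_vs_textured_low(self, textured):
        flat = np.full_like(textured, textured.mean())
        assert ssim(flat, textured) < 0.5

    def test_monotone_in_noise(self, textured):
        rng = np.random.default_rng(5)
        vals = [ssim(textured + rng.normal(0, s, textured.shape), textured)
                for s in (0.01, 0.05, 0.1)]
        assert vals[0] > vals[1] > vals[2]

    def test_symmetry(self, textured):
        x = textured + np.random.default_rng(2).normal(0, 0.03, textured.shape)
        dr = float(textured.max() - textured.min())
        assert ssim(x, textured, data_range=dr) == \
            pytest.approx(ssim(textured, x, data_range=dr), abs=1e-9)


class TestFSIM:
    def test_identity(self, textured):
        assert fsim(textured, textured) == pytest.approx(1.0)

    def test_bounded_in_unit_interval(self, textured):
        rng = np.random.default_rng(3)
        for _ in range(3):
            x = np.clip(textured + rng.normal(0, 0.2, textured.shape), 0, 1)
            v = fsim(x, textured)
            assert 0.0 < v <= 1.0

    def test_monotone_in_blur(self, textured):
        vals = [fsim(ndi.gaussian_filter(textured, b) if b else textured,
                     textured) for b in (0, 2, 4)]
        assert vals[0] > vals[1] > vals[2]


class TestEvaluate:
    def _dataset(self, n=2, size=24, perfect=True):
        from sparsect.training import PairedDataset
        rng = np.random.default_rng(0)
        gt = np.stack([ndi.gaussian_filter(rng.random((size, size)), 1.5)
                       for _ in range(n)]).astype(np.float32)
        y = gt.copy() if perfect else \
            gt + rng.normal(0, 0.05, gt.shape).astype(np.float32)
        return PairedDataset(y=y, gt=gt, geometry_tag="custom",
                             noise_level=0.0)

    def test_passthrough_on_perfect_pairs(self):
        rep = evaluate(None, self._dataset(perfect=True))
        assert rep.means["re"] == 0.0
        assert rep.means["ssim"] == pytest.approx(1.0)

    def test_single_pair_mean_equals_value(self):
        rep = evaluate(None, self._dataset(n=1, perfect=False))
        assert rep.means["re"] == rep.per_image["re"][0]

    def test_report_serialization(self, tmp_path):
        rep = evaluate(None, self._dataset(perfect=False))
        rep.to_csv(tmp_path / "r.csv")
        d = rep.to_json()
        assert d["n_images"] == 2 and "re" in d["means"]
        text = (tmp_path / "r.csv").read_text()
        assert text.startswith("image,re,") and "mean," in text
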