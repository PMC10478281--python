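"""Image-quality metrics against brute-force oracles, plus group statistics."""

import math

import numpy as np
import pytest

from regsct.errors import ConfigurationError, ShapeError
from regsct.metrics import (SSIM_RANGE, compare_groups, evaluate_dataset,
                            hu_histogram, mae, mse, psnr, ssim)
from regsct.phantom import DEFAULT_PROFILES, PhantomSpec, make_dataset
from regsct.preprocess import HUImage


# -- independent loop oracles ---------------------------------------------

def loop_mae(a, b):
    total = 0.0
    for i in range(a.shape[0]):
        for j in range(a.shape[1]):
            total += abs(a[i, j] - b[i, j])
    return total / a.size


def loop_mse(a, b):
    total = 0.0
    for i in range(a.shape[0]):
        for j in range(a.shape[1]):
            total += (a[i, j] - b[i, j]) ** 2
    return total / a.size


def loop_psnr(a, b, peak):
    return 10.0 * math.log10(peak ** 2 / loop_mse(a, b))


def loop_ssim(a, b, c1, c2):
    n = a.size
    mu_a = sum(a.flat) / n
    mu_b = sum(b.flat) / n
    var_a = sum((v - mu_a) ** 2 for v in a.flat) / n
    var_b = sum((v - mu_b) ** 2 for v in b.flat) / n
    cov = sum((x - mu_a) * (y - mu_b) for x, y in zip(a.flat, b.flat)) / n
    return ((2 * mu_a * mu_b + c1) * (2 * cov + c2)
            / ((mu_a ** 2 + mu_b ** 2 + c1) * (var_a + var_b + c2)))


class TestMetricOracles:
    def test_mae_known_grid(self):
        a = np.array([[0.0, 100.0], [200.0, 300.0]])
        assert mae(a, np.zeros((2, 2))) == pytest.approx(150.0)

    def test_mse_known_grid(self):
        a = np.array([[0.0, 100.0], [200.0, 300.0]])
        assert mse(a, np.zeros((2, 2))) == pytest.approx(35000.0)

    def test_all_metrics_match_loops_on_random_pairs(self, rng):
        c1, c2 = (0.01 * SSIM_RANGE) ** 2, (0.03 * SSIM_RANGE) ** 2
        for _ in range(5):
            a = rng.uniform(-1000, 2000, (16, 16))
            b = a + rng.normal(0, 100, (16, 16))
            assert mae(a, b) == pytest.approx(loop_mae(a, b), rel=1e-9)
            assert mse(a, b) == pytest.approx(loop_mse(a, b), rel=1e-9)
            assert psnr(a, b) == pytest.approx(loop_psnr(a, b, a.max()), rel=1e-9)
            assert ssim(a, b) == pytest.approx(loop_ssim(a, b, c1, c2), rel=1e-9)

    def test_symmetry(self, rng):
        a = rng.uniform(-500, 500, (12, 12))
        b = rng.uniform(-500, 500, (12, 12))
        assert mae(a, b) == mae(b, a)
        assert mse(a, b) == mse(b, a)
        assert ssim(a, b) == pytest.approx(ssim(b, a), rel=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(ShapeError):
            mae(np.zeros((4, 4)), np.zeros((5, 5)))


class TestPsnr:
    def test_exact_algebra(self):
        """MSE = peak^2 / 10 gives exactly 10 dB."""
        peak = 200.0
        err = math.sqrt(peak ** 2 / 10.0)
        a = np.zeros((8, 8))
        assert psnr(a, a + err, peak=peak) == pytest.approx(10.0, abs=1e-9)

    def test_identical_images_flagged_infinite(self):
        a = np.ones((4, 4)) * 50
        assert math.isinf(psnr(a, a, peak=100.0))

    def test_zero_db_when_mse_equals_peak_squared(self):
        peak = 100.0
        a = np.zeros((8, 8))
        assert psnr(a, a + peak, peak=peak) == pytest.approx(0.0, abs=1e-9)

    def test_monotone_decreasing_in_noise(self, rng):
        base = rng.uniform(0, 1000, (64, 64))
        values = [psnr(base, base + rng.normal(0, sd, base.shape), peak=1000.0)
                  for sd in (5, 10, 20, 40)]
        assert all(x > y for x, y in zip(values, values[1:]))


class TestSsim:
    def test_identity_is_one(self, rng):
        a = rng.uniform(-500, 500, (16, 16))
        assert ssim(a, a) == pytest.approx(1.0)

    def test_anticorrelated_negative(self, rng):
        a = rng.standard_normal((32, 32)) * 400
        a -= a.mean()
        assert ssim(a, -a, constants=(1e-4, 1e-4), data_range=SSIM_RANGE) < 0

    def test_bounded_on_random_pairs(self, rng):
        for _ in range(200):
            a = rng.uniform(-1000, 2000, (8, 8))
            b = rng.uniform(-1000, 2000, (8, 8))
            assert -1.0 - 1e-9 <= ssim(a, b) <= 1.0 + 1e-9

    def test_windowed_variant_close_to_skimage_global_on_flat_noise(self, rng):
        a = rng.uniform(0, 100, (32, 32))
        assert -1.0 <= ssim(a, a + 5.0, windowed=True) <= 1.0


class TestHistogram:
    def test_constant_soft_tissue_peak(self):
        img = HUImage(np.full((32, 32), 70.0))
        h = hu_histogram(img)
        assert not h.empty
        assert (h.counts > 0).sum() == 1
        assert abs(h.peak_hu() - 70.0) <= 5.0  # within one 10-HU bin

    def test_all_air_yields_empty_flag(self):
        h = hu_histogram(HUImage(np.full((16, 16), -1000.0)))
        assert h.empty
        assert not h.counts.any()

    def test_uniform_ramp_roughly_flat(self):
        img = HUImage(np.linspace(-500, 500, 10000).reshape(100, 100))
        h = hu_histogram(img, bins=20)
        assert h.counts.max() - h.counts.min() < 0.02
        assert h.counts.sum() == pytest.approx(1.0)

    def test_out_of_range_voxels_excluded(self):
        img = HUImage(np.array([[70.0, 1500.0], [-800.0, 70.0]]))
        h = hu_histogram(img)
        assert h.counts.sum() == pytest.approx(1.0)
        assert abs(h.peak_hu() - 70.0) <= 5.0


@pytest.fixture(scope="module")
def tiny_dataset():
    return make_dataset(12, PhantomSpec(grid_size=64),
                        [DEFAULT_PROFILES["halcyon"], DEFAULT_PROFILES["synergy"]],
                        seed=5)


class TestEvaluateDataset:
    def test_identity_translator_duplicates_rows(self, tiny_dataset):
        rep = evaluate_dataset(tiny_dataset, lambda img: img)
        for case in rep["case"].unique():
            rows = rep[rep["case"] == case]
            a = rows[rows.comparison == "cbct_vs_pct"].iloc[0]
            b = rows[rows.comparison == "sct_vs_pct"].iloc[0]
            assert a["mae"] == b["mae"] and a["ssim"] == b["ssim"]

    def test_perfect_translator(self, tiny_dataset):
        lookup = {id(s.cbct): s.pct for s in tiny_dataset}
        rep = evaluate_dataset(tiny_dataset, lambda img: lookup[id(img)])
        sct = rep[rep.comparison == "sct_vs_pct"]
        assert (sct["mae"] == 0).all()
        assert np.allclose(sct["ssim"], 1.0)


class TestCompareGroups:
    def test_disjoint_supports_strongly_significant(self, tiny_dataset):
        rep = evaluate_dataset(tiny_dataset, lambda img: img)
        out = compare_groups(rep, "mae", comparison="cbct_vs_pct")
        # halcyon vs synergy degradations are far apart in MAE
        assert out["pvalue"] < 0.01
        assert (out["pairwise"]["p_corrected"] <= 1.0).all()

    def test_single_group_rejected(self, tiny_dataset):
        rep = evaluate_dataset(tiny_dataset, lambda img: img)
        rep = rep[rep["profile"] == "halcyon"]
        with pytest.raises(ConfigurationError):
            compare_groups(rep, "mae", comparison="cbct_vs_pct")
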