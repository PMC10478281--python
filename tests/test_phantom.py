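"""Phantom generation, CBCT degradation, and dataset reproducibility."""

import numpy as np
import pytest
from scipy.ndimage import binary_erosion

from regsct.errors import ConfigurationError
from regsct.phantom import (DEFAULT_PROFILES, DegradationProfile, PhantomSpec,
                            degrade_to_cbct, generate_phantom, make_dataset,
                            random_deformation, sample_seed, synthetic_dose)
from regsct.warp import warp, field_magnitude


IDENTITY_PROFILE = DegradationProfile("custom")
WARP_ONLY_PROFILE = DegradationProfile("custom", deform_amplitude=3.0)


class TestGeneratePhantom:
    def test_plain_phantom_has_exactly_three_tissue_values(self, plain_spec):
        img = generate_phantom(plain_spec, seed=7)
        assert set(np.unique(img.values)) == {-1000.0, plain_spec.tissue_hu,
                                              plain_spec.bone_hu}

    def test_deterministic_given_spec_and_seed(self, small_spec):
        a = generate_phantom(small_spec, seed=3)
        b = generate_phantom(small_spec, seed=3)
        assert np.array_equal(a.values, b.values)

    def test_seeds_give_different_geometry(self, small_spec):
        a = generate_phantom(small_spec, seed=3)
        b = generate_phantom(small_spec, seed=4)
        assert not np.array_equal(a.values, b.values)

    def test_too_small_grid_rejected(self):
        with pytest.raises(ConfigurationError, match="grid_size"):
            generate_phantom(PhantomSpec(grid_size=16), seed=0)

    def test_invalid_hu_bounds_rejected(self):
        with pytest.raises(ConfigurationError, match="air_hu"):
            PhantomSpec(air_hu=-1500).validate()
        with pytest.raises(ConfigurationError, match="bone_hu"):
            PhantomSpec(bone_hu=2500).validate()


class TestRandomDeformation:
    def test_zero_amplitude_is_zero_field(self):
        f = random_deformation((32, 32), 0.0, 8.0, seed=0)
        assert not f.any()

    @pytest.mark.parametrize("seed", [0, 9])
    def test_peak_magnitude_equals_amplitude(self, seed):
        f = random_deformation((64, 64), 5.0, 8.0, seed=seed)
        assert abs(field_magnitude(f).max() - 5.0) < 1e-5

    def test_seeds_differ(self):
        a = random_deformation((32, 32), 2.0, 4.0, seed=1)
        b = random_deformation((32, 32), 2.0, 4.0, seed=2)
        assert (a != b).any()

    def test_nonpositive_smoothness_rejected(self):
        with pytest.raises(ConfigurationError):
            random_deformation((32, 32), 2.0, 0.0, seed=1)


class TestDegradeToCbct:
    def test_identity_profile_is_bit_exact(self, small_spec):
        pct = generate_phantom(small_spec, seed=5)
        cbct, f = degrade_to_cbct(pct, IDENTITY_PROFILE, seed=5)
        assert np.array_equal(cbct.values, pct.values)
        assert not f.any()

    def test_deterministic(self, small_spec):
        pct = generate_phantom(small_spec, seed=5)
        a, fa = degrade_to_cbct(pct, DEFAULT_PROFILES["synergy"], seed=11)
        b, fb = degrade_to_cbct(pct, DEFAULT_PROFILES["synergy"], seed=11)
        assert np.array_equal(a.values, b.values)
        assert np.array_equal(fa, fb)

    def test_synergy_mean_body_shift_matches_profile(self, plain_spec):
        """On a constant-tissue slice, the mean degradation inside the body
        approximates the profile's global HU shift (cupping adds a small
        known positive bias, noise averages out)."""
        profile = DEFAULT_PROFILES["synergy"]
        pct = generate_phantom(plain_spec, seed=2)
        cbct, _ = degrade_to_cbct(pct, profile, seed=2)
        tissue = np.isclose(pct.values, plain_spec.tissue_hu)
        core = binary_erosion(tissue, iterations=8)  # clear of warped borders
        assert core.sum() > 200
        mean_shift = float((cbct.values - pct.values)[core].mean())
        assert abs(mean_shift - profile.hu_shift) < 20.0


class TestMakeDataset:
    def test_cycles_profiles(self, small_spec):
        profiles = list(DEFAULT_PROFILES.values())
        ds = make_dataset(4, small_spec, profiles, seed=0)
        assert [s.profile_name for s in ds] == [p.name for p in profiles]

    def test_reproducible_from_master_seed(self, small_spec):
        a = make_dataset(6, small_spec, [DEFAULT_PROFILES["halcyon"]], seed=42)
        b = make_dataset(6, small_spec, [DEFAULT_PROFILES["halcyon"]], seed=42)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.pct.values, sb.pct.values)
            assert np.array_equal(sa.cbct.values, sb.cbct.values)
            assert np.array_equal(sa.true_field, sb.true_field)

    def test_single_sample_reproducible_in_isolation(self, small_spec):
        """The recorded per-sample seed regenerates that sample alone."""
        ds = make_dataset(5, small_spec, [DEFAULT_PROFILES["trilogy"]], seed=9)
        s = ds[3]
        assert s.seed == sample_seed(9, 3)
        pct = generate_phantom(small_spec, s.seed)
        cbct, f = degrade_to_cbct(pct, DEFAULT_PROFILES["trilogy"], s.seed + 1)
        assert np.array_equal(pct.values, s.pct.values)
        assert np.array_equal(cbct.values, s.cbct.values)

    def test_empty_inputs_rejected(self, small_spec):
        with pytest.raises(ConfigurationError):
            make_dataset(0, small_spec, [IDENTITY_PROFILE], seed=0)
        with pytest.raises(ConfigurationError):
            make_dataset(3, small_spec, [], seed=0)

    def test_all_images_within_hu_window(self, small_spec):
        ds = make_dataset(100, small_spec, list(DEFAULT_PROFILES.values()), seed=1)
        for s in ds:
            for img in (s.pct, s.cbct):
                assert img.values.min() >= -1000.0
                assert img.values.max() <= 2000.0

    def test_true_field_explains_misalignment(self, small_spec):
        """Under warp-only degradation the CBCT equals pct warped by the
        recorded field up to interpolation error."""
        ds = make_dataset(3, small_spec, [WARP_ONLY_PROFILE], seed=17)
        for s in ds:
            rewarped = warp(s.pct.values, s.true_field)
            assert np.abs(rewarped - s.cbct.values).mean() < 1.0


class TestSyntheticDose:
    def test_uniform(self):
        d = synthetic_dose((10, 10), "uniform", {"dose": 60.0})
        assert (d == 60.0).all()

    def test_linear_gradient_midpoint(self):
        d = synthetic_dose((9, 9), "linear_gradient", {"low": 0.0, "high": 60.0})
        assert d[0, 4] == pytest.approx(30.0)

    def test_gaussian_blob_peak(self):
        d = synthetic_dose((33, 33), "gaussian_blob", {"peak": 70.0})
        assert abs(d.max() - 70.0) < 1e-9

    def test_unknown_kind_rejected(self):
        with pytest.raises(ConfigurationError, match="unknown dose kind"):
            synthetic_dose((8, 8), "conformal_arc")
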