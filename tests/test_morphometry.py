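"""Segmentation and feature extraction against analytic shapes and
hand-rolled brute-force oracles."""

import numpy as np
import pytest

from spheromet.morphometry import (
    EmptySegmentationError,
    GranularitySpectrum,
    SpheroidMask,
    filter_granularity,
    granularity_spectrum,
    segment_spheroid,
    shape_features,
)
from spheromet.synthgen import ImageSpec, make_spheroid_image

from _oracles import granulometry_oracle, shape_features_oracle
from conftest import random_blob_mask


def disc_mask(radius: int, margin: int = 10) -> np.ndarray:
    n = 2 * radius + 2 * margin
    yy, xx = np.mgrid[0:n, 0:n]
    c = (n - 1) / 2
    return np.hypot(yy - c, xx - c) <= radius


class TestSegmentation:
    def test_disc_area_within_two_percent(self, clean_disc):
        mask = segment_spheroid(clean_disc.image)
        assert mask.mask.sum() == pytest.approx(np.pi * 50**2, rel=0.02)

    def test_blank_image_raises(self):
        with pytest.raises(EmptySegmentationError):
            segment_spheroid(np.full((64, 64), 0.5))

    def test_two_discs_larger_kept(self):
        img = np.full((200, 320), 0.1)
        yy, xx = np.mgrid[0:200, 0:320]
        img[np.hypot(yy - 100, xx - 80) <= 30] = 0.9
        img[np.hypot(yy - 100, xx - 230) <= 50] = 0.9
        mask = segment_spheroid(img)
        assert mask.mask.sum() == pytest.approx(np.pi * 50**2, rel=0.02)
        # the kept object is the right-hand disc
        assert np.nonzero(mask.mask)[1].mean() > 160

    def test_dark_polarity(self):
        si = make_spheroid_image(ImageSpec(radius=40, seed=3, polarity="dark"))
        mask = segment_spheroid(si.image, polarity="dark")
        assert mask.mask.sum() == pytest.approx(np.pi * 40**2, rel=0.02)

    def test_holes_filled(self):
        img = np.full((128, 128), 0.1)
        yy, xx = np.mgrid[0:128, 0:128]
        rad = np.hypot(yy - 64, xx - 64)
        img[rad <= 40] = 0.9
        img[rad <= 10] = 0.1  # interior hole
        mask = segment_spheroid(img)
        assert mask.mask.sum() == pytest.approx(np.pi * 40**2, rel=0.02)

    def test_mask_invariants_enforced(self):
        two = np.zeros((32, 32), bool)
        two[2:6, 2:6] = True
        two[20:24, 20:24] = True
        with pytest.raises(ValueError, match="connected component"):
            SpheroidMask(two).validate()


class TestShapeFeatures:
    def test_disc_reference_values(self):
        f = shape_features(SpheroidMask(disc_mask(50)))
        assert 0.95 <= f.form_factor <= 1.05
        assert 0.98 <= f.solidity <= 1.0
        assert 0.95 <= f.compactness <= 1.05
        assert f.median_radius == pytest.approx(50 * (1 - 1 / np.sqrt(2)), rel=0.1)

    def test_square_form_factor_approaches_pi_over_4(self):
        m = np.zeros((220, 220), bool)
        m[10:210, 10:210] = True
        f = shape_features(SpheroidMask(m))
        assert f.form_factor == pytest.approx(np.pi / 4, rel=0.05)
        assert f.area == 200 * 200
        assert f.compactness == pytest.approx(np.pi / 3, rel=0.02)

    @pytest.mark.parametrize("seed", range(20))
    def test_oracle_equivalence_on_random_blobs(self, seed):
        m = random_blob_mask(seed)
        got = shape_features(SpheroidMask(m))
        ref = shape_features_oracle(m)
        assert got.area == ref["area"]
        assert got.perimeter == pytest.approx(ref["perimeter"], rel=1e-6)
        assert got.form_factor == pytest.approx(ref["form_factor"], rel=1e-6)
        assert got.compactness == pytest.approx(ref["compactness"], rel=1e-6)
        assert got.solidity == pytest.approx(ref["solidity"], rel=1e-6)
        assert got.median_radius == pytest.approx(ref["median_radius"], rel=1e-6)

    def test_rotation_invariance_90_degrees(self):
        m = random_blob_mask(3)
        f0 = shape_features(SpheroidMask(m))
        f90 = shape_features(SpheroidMask(np.rot90(m)))
        for attr in ("form_factor", "solidity", "compactness"):
            assert getattr(f90, attr) == pytest.approx(getattr(f0, attr), rel=0.03)

    def test_scale_equivariance(self):
        small = disc_mask(25)
        big = disc_mask(50)
        fs, fb = shape_features(SpheroidMask(small)), shape_features(SpheroidMask(big))
        assert fb.area / fs.area == pytest.approx(4, rel=0.03)
        assert fb.perimeter / fs.perimeter == pytest.approx(2, rel=0.03)
        for attr in ("form_factor", "solidity", "compactness"):
            assert getattr(fb, attr) == pytest.approx(getattr(fs, attr), rel=0.03)


class TestGranularity:
    def test_uniform_object_has_no_small_scale_mass(self):
        m = disc_mask(20, margin=8)
        img = np.where(m, 0.8, 0.0)
        spec = granularity_spectrum(img, SpheroidMask(m), n_scales=6)
        assert np.all(spec.values[:3] <= 1.0)

    def test_speckle_grain_located(self):
        si = make_spheroid_image(
            ImageSpec(width=180, height=180, radius=60, texture_grain=4, seed=2)
        )
        mask = segment_spheroid(si.image)
        spec = granularity_spectrum(si.image, mask, n_scales=8)
        peak_scale = spec.scales[int(np.argmax(spec.values))]
        assert abs(peak_scale - 4) <= 1

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        m = disc_mask(18, margin=14)  # 64x64 frame
        img = np.where(m, 0.5 + 0.3 * rng.random(m.shape), 0.0)
        got = granularity_spectrum(img, SpheroidMask(m), n_scales=4)
        ref = granulometry_oracle(img, m, n_scales=4)
        np.testing.assert_allclose(got.values, ref, atol=1e-9)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            granularity_spectrum(np.ones((8, 8)), SpheroidMask(np.zeros((8, 8), bool)))


class TestGranularityFilter:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ([40, 10, 3, 1.5, 1], [0, 1, 2]),  # cutoff 2.0
            ([7], [0]),
            ([2, 2, 2], [0, 1, 2]),
        ],
    )
    def test_relative_threshold_rule(self, values, expected):
        spec = GranularitySpectrum(np.arange(1, len(values) + 1), np.array(values, float))
        assert filter_granularity(spec) == expected

    def test_argmax_always_kept(self):
        spec = GranularitySpectrum(np.arange(1, 4), np.array([0.001, 100.0, 0.002]))
        kept = filter_granularity(spec)
        assert 1 in kept

    def test_all_zero_keeps_nothing(self):
        spec = GranularitySpectrum(np.arange(1, 4), np.zeros(3))
        assert filter_granularity(spec) == []
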