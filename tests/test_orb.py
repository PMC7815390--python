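"""FAST detection, region balancing, orientation and BRIEF descriptors."""

import numpy as np
import pytest
from scipy import ndimage

from exprfeat import (
    RegionGrid,
    RegionOrbFeaturizer,
    SamplingPattern,
    brief_descriptor,
    detect_region_balanced,
    fast_is_corner,
    fast_score,
    orb_feature,
    orientation,
)
from exprfeat.orb import BorderError, ConfigurationError, Corner, smooth
from exprfeat.synthetic import make_clustered_corner_image, make_corner_grid_image

from conftest import oracle_brief, oracle_fast_is_corner


def _textured_image(seed, size=96):
    """Smooth random texture with enough structure to orient and describe."""
    rng = np.random.default_rng(seed)
    img = ndimage.gaussian_filter(rng.uniform(0, 255, (size, size)), 3)
    img = 128 + 3.0 * (img - img.mean())
    return np.clip(img, 0, 255)


class TestFastSegmentTest:
    def test_constant_image_has_no_corners(self):
        img = np.full((20, 20), 90)
        assert not fast_is_corner(img, (10, 10), t=10)
        assert fast_score(img, (10, 10), t=10) == 0.0

    def test_isolated_blob_and_square_corner(self):
        img = np.zeros((40, 40))
        img[19:22, 19:22] = 200  # 3x3 blob: whole ring darker -> run of 16
        assert fast_is_corner(img, (20, 20), t=30)
        img = np.zeros((40, 40))
        img[15:35, 15:35] = 200
        # a perfect right angle leaves a dark arc of only 11 < 12: the
        # segment test and the oracle must agree it is not detected
        for p in [(15, 15), (16, 16), (14, 14)]:
            assert fast_is_corner(img, p, t=30) == oracle_fast_is_corner(img, *p, 30)

    def test_disk_image_matches_oracle(self):
        img = np.zeros((30, 30))
        rr, cc = np.mgrid[:30, :30]
        img[(rr - 15) ** 2 + (cc - 15) ** 2 <= 9] = 255
        for p in [(15, 15), (13, 13), (12, 15), (15, 12)]:
            assert fast_is_corner(img, p, 50) == oracle_fast_is_corner(img, *p, 50)

    def test_border_error(self):
        with pytest.raises(BorderError):
            fast_is_corner(np.zeros((20, 20)), (2, 10), t=10)

    def test_oracle_equivalence_random_images(self):
        rng = np.random.default_rng(21)
        for _ in range(3):
            img = rng.integers(0, 256, (24, 24)).astype(float)
            for t in (10, 60):
                for r in range(3, 21):
                    for c in range(3, 21):
                        assert fast_is_corner(img, (r, c), t) == \
                            oracle_fast_is_corner(img, r, c, t), (r, c, t)


class TestFastScore:
    def test_single_excess_pixel(self):
        img = np.full((20, 20), 100.0)
        img[10 - 3, 10] = 100 + 20 + 5  # one circle pixel at I_p + t + 5
        assert fast_score(img, (10, 10), t=20) == pytest.approx(5.0)

    def test_monotone_in_contrast(self):
        strong = np.zeros((40, 40))
        strong[15:35, 15:35] = 200
        weak = strong / 2
        assert fast_score(strong, (15, 15), 30) > fast_score(weak, (15, 15), 30)


class TestRegionBalancedDetection:
    def test_exact_budget_and_per_region_counts(self):
        img, centers = make_corner_grid_image(per_region=12, seed=5)
        grid = RegionGrid(4, 4, 160)
        corners = detect_region_balanced(img, grid, t0=30)
        assert len(corners) == 160
        counts = np.bincount([c.region_index for c in corners], minlength=16)
        assert (counts == 10).all()  # T = 160 / 16
        planted = np.array(centers)
        for c in corners:
            assert (np.abs(planted - [c.row, c.col]).max(axis=1) <= 1).any()

    def test_remainder_rule(self):
        img, _ = make_corner_grid_image(per_region=12, seed=6)
        corners = detect_region_balanced(img, RegionGrid(4, 4, 150), t0=30)
        assert len(corners) == 150
        counts = np.bincount([c.region_index for c in corners], minlength=16)
        assert sorted(counts)[:10] == [9] * 10 and sorted(counts)[10:] == [10] * 6

    def test_single_region_degenerates_to_global(self):
        img, _ = make_corner_grid_image(per_region=12, seed=7)
        grid1 = RegionGrid(1, 1, 40)
        corners = detect_region_balanced(img, grid1, t0=30)
        assert len(corners) == 40
        # returned in descending score order within the single region
        scores = [c.score for c in corners]
        assert scores == sorted(scores, reverse=True)

    def test_constant_image_warns_and_returns_empty(self):
        img = np.full((130, 130), 80)
        with pytest.warns(UserWarning, match="zero-padded"):
            corners = detect_region_balanced(img, RegionGrid(4, 4, 160), t0=30)
        assert corners == []

    def test_nms_separation_within_region(self):
        img, _ = make_clustered_corner_image(seed=8)
        corners = detect_region_balanced(img, RegionGrid(4, 4, 160), t0=30)
        by_region = {}
        for c in corners:
            by_region.setdefault(c.region_index, []).append(c)
        for group in by_region.values():
            for a in group:
                for b in group:
                    if a is not b:
                        assert max(abs(a.row - b.row), abs(a.col - b.col)) > 1

    def test_region_balance_reduces_count_variance(self):
        img, _ = make_clustered_corner_image(seed=9)
        size = img.shape[0]
        edges = np.linspace(0, size, 5).astype(int)

        def counts(corners):
            out = np.zeros(16)
            for c in corners:
                i = np.searchsorted(edges, c.row, side="right") - 1
                j = np.searchsorted(edges, c.col, side="right") - 1
                out[i * 4 + j] += 1
            return out

        balanced = detect_region_balanced(img, RegionGrid(4, 4, 160), t0=30)
        global_top = detect_region_balanced(img, RegionGrid(1, 1, 160), t0=30)
        assert counts(balanced).var() < counts(global_top).var()

    def test_configuration_errors(self):
        with pytest.raises(ConfigurationError):
            RegionGrid(5, 5, 20)  # more regions than budget
        with pytest.raises(ValueError):
            detect_region_balanced(np.zeros((20, 20)), RegionGrid(4, 4, 160))


class TestOrientation:
    def test_symmetric_patch_is_zero(self):
        assert orientation(np.full((40, 40), 50.0), (20, 20), radius=10) == 0.0

    def test_bright_positive_x_half(self):
        img = np.zeros((40, 40))
        img[:, 21:] = 200  # bright to the right of the center column
        assert orientation(img, (20, 20), radius=10) == pytest.approx(0.0, abs=1e-9)

    def test_quarter_turn_shifts_angle(self):
        img = _textured_image(31, 64)
        theta0 = orientation(img, (32, 32), radius=15)
        rot = np.rot90(img, k=-1)  # 90 degrees clockwise = +pi/2 in (row, col)
        theta1 = orientation(rot, (32, 31), radius=15)
        diff = np.angle(np.exp(1j * (theta1 - theta0 - np.pi / 2)))
        assert abs(diff) < 0.1

    def test_border_error(self):
        with pytest.raises(BorderError):
            orientation(np.zeros((20, 20)), (5, 5), radius=10)


class TestBrief:
    def test_pattern_is_reproducible_and_in_window(self):
        p1 = SamplingPattern.generate(seed=42)
        p2 = SamplingPattern.generate(seed=42)
        assert p1.pairs.shape == (256, 4)
        np.testing.assert_array_equal(p1.pairs, p2.pairs)
        assert np.abs(p1.pairs).max() <= 15
        assert not np.array_equal(p1.pairs, SamplingPattern.generate(seed=43).pairs)

    def test_constant_image_all_zero_bits(self):
        img = np.full((64, 64), 128.0)
        bits = brief_descriptor(img, (32, 32), SamplingPattern.generate(), steered=False)
        assert bits.shape == (256,)
        assert (bits == 0).all()  # equality comparisons yield 0

    def test_affine_intensity_invariance(self):
        pattern = SamplingPattern.generate()
        for seed in range(5):
            img = _textured_image(seed)
            b0 = brief_descriptor(img, (48, 48), pattern, steered=False)
            b1 = brief_descriptor(2.5 * img + 17.0, (48, 48), pattern, steered=False)
            np.testing.assert_array_equal(b0, b1)

    def test_matches_literal_oracle(self):
        pattern = SamplingPattern.generate()
        img = _textured_image(33)
        smoothed = smooth(img)
        got = brief_descriptor(img, (40, 52), pattern, steered=False)
        np.testing.assert_array_equal(got, oracle_brief(smoothed, 40, 52, pattern.pairs))

    def test_border_error(self):
        with pytest.raises(BorderError):
            brief_descriptor(np.zeros((64, 64)), (10, 32), SamplingPattern.generate())

    def test_steering_rotates_lookup(self):
        img = _textured_image(34)
        c = Corner(48, 48, 1.0, theta=0.3)
        pattern = SamplingPattern.generate()
        steered = brief_descriptor(img, c, pattern, steered=True)
        plain = brief_descriptor(img, c, pattern, steered=False)
        assert (steered != plain).any()


class TestOrbFeature:
    def test_length_padding_and_determinism(self):
        img, _ = make_corner_grid_image(size=130, per_region=4, seed=10)
        grid = RegionGrid(4, 4, 64)
        pattern = SamplingPattern.generate()
        f1 = orb_feature(img, grid, pattern)
        f2 = orb_feature(img, grid, pattern)
        assert len(f1) == 64 * 256
        np.testing.assert_array_equal(f1.bits, f2.bits)
        assert set(np.unique(f1.bits)) <= {0, 1}

    def test_flat_image_zero_padded(self):
        with pytest.warns(UserWarning):
            f = orb_feature(np.full((130, 130), 40), RegionGrid(4, 4, 32))
        assert (f.bits == 0).all()
        assert not f.valid.any()

    def test_featurizer_roundtrip(self):
        img, _ = make_corner_grid_image(size=130, per_region=4, seed=11)
        fz = RegionOrbFeaturizer(n_keypoints=32, grid_m=2, grid_n=2)
        X = fz.fit([img]).transform(np.stack([img, img]))
        assert X.shape == (2, 32 * 256)
        np.testing.assert_array_equal(X[0], X[1])
        assert fz.get_params()["n_keypoints"] == 32
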