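"""Shape feature oracles: 2D descriptors, Hu invariants, 3D sphericity."""

import numpy as np
import pytest

from nodulecad import PhantomSpec, RoiVolume, make_roi
from nodulecad.roi import RoiSlice
from nodulecad.shape import (
    area,
    circularity,
    elongation,
    ercld,
    esv,
    euler_number,
    hu_moments,
    perimeter,
    rectangularity,
    scdstd,
    shape_feature_block,
)


def slice_of(mask, img=None):
    mask = np.asarray(mask, bool)
    return RoiSlice(np.ones(mask.shape) if img is None else img, mask)


def disk_mask(radius, pad=1):
    """Lattice-enumeration oracle: pixels with x^2 + y^2 <= r^2."""
    n = 2 * (radius + pad) + 1
    y, x = np.indices((n, n)) - (radius + pad)
    return x**2 + y**2 <= radius**2


class TestArea:
    def test_full_square(self):
        assert area(slice_of(np.ones((5, 5)))) == 25

    def test_single_pixel(self):
        m = np.zeros((3, 3))
        m[1, 1] = 1
        assert area(slice_of(m)) == 1

    def test_digitized_disk_matches_enumeration(self):
        m = disk_mask(10)
        enumerated = sum(
            1 for x in range(-10, 11) for y in range(-10, 11) if x * x + y * y <= 100
        )
        assert area(slice_of(m)) == enumerated == 317


class TestPerimeter:
    @pytest.mark.parametrize("side,expected", [(1, 1), (3, 8), (5, 16)])
    def test_solid_square_boundary_count(self, side, expected):
        m = np.zeros((side + 2, side + 2))
        m[1 : side + 1, 1 : side + 1] = 1
        assert perimeter(slice_of(m)) == expected

    def test_mask_touching_grid_edge_counts_as_boundary(self):
        assert perimeter(slice_of(np.ones((3, 3)))) == 8


class TestPlanarDescriptors:
    def test_circularity_square_and_pixel(self):
        m = np.zeros((5, 5))
        m[1:4, 1:4] = 1
        assert circularity(slice_of(m)) == pytest.approx(64 / (4 * np.pi * 9))
        p = np.zeros((3, 3))
        p[1, 1] = 1
        assert circularity(slice_of(p)) == pytest.approx(1 / (4 * np.pi))

    def test_circularity_rises_with_elongation_at_equal_area(self):
        bar = np.zeros((3, 22))
        bar[1, 1:21] = 1  # 1x20
        rect = np.zeros((6, 7))
        rect[1:5, 1:6] = 1  # 4x5
        assert circularity(slice_of(bar)) > circularity(slice_of(rect))

    def test_rectangularity(self):
        rect = np.zeros((6, 9))
        rect[1:5, 2:8] = 1
        assert rectangularity(slice_of(rect)) == 1.0
        assert rectangularity(slice_of(disk_mask(10))) == pytest.approx(317 / (21 * 21))
        diag = np.eye(5)
        assert rectangularity(slice_of(diag)) == pytest.approx(0.2)

    def test_elongation(self):
        box = np.zeros((5, 14))
        box[1:4, 1:13] = 1
        assert elongation(slice_of(box)) == pytest.approx(3 / 12)
        assert elongation(slice_of(disk_mask(10))) == 1.0

    def test_euler_number_components_minus_holes(self):
        assert euler_number(slice_of(disk_mask(6))) == 1
        annulus = disk_mask(6) & ~disk_mask(3, pad=4)
        assert euler_number(slice_of(annulus)) == 0
        # two disjoint disks, one holed: 2 components - 1 hole
        two = np.zeros((15, 32), bool)
        two[:15, :15] = disk_mask(6)
        two[3:12, 20:29] = disk_mask(3, pad=1)
        two[6:9, 23:26] = False
        assert euler_number(slice_of(two)) == 2 - 1


class TestHuMoments:
    def _shape(self):
        rng = np.random.default_rng(3)
        m = np.zeros((18, 18), bool)
        m[4:14, 3:15] = True
        m[6:9, 5:8] = False
        return m, rng.uniform(1, 2, (18, 18))

    def test_translation_invariance(self):
        m, img = self._shape()
        big = np.zeros((40, 40), bool)
        img2 = np.zeros((40, 40))
        big[7 : 7 + 18, 3 : 3 + 18] = m
        img2[7 : 7 + 18, 3 : 3 + 18] = img
        h1 = hu_moments(RoiSlice(img, m)).compressed
        h2 = hu_moments(RoiSlice(img2, big)).compressed
        np.testing.assert_allclose(h1, h2, atol=1e-8)

    def test_rotation_invariance_90deg(self):
        m, img = self._shape()
        h1 = hu_moments(RoiSlice(img, m)).compressed
        h2 = hu_moments(RoiSlice(np.rot90(img), np.rot90(m))).compressed
        np.testing.assert_allclose(h1, h2, atol=1e-8)

    def test_scale_invariance_2x_nearest_neighbor(self):
        m, img = self._shape()
        h1 = hu_moments(RoiSlice(img, m)).compressed
        h2 = hu_moments(
            RoiSlice(np.kron(img, np.ones((2, 2))), np.kron(m, np.ones((2, 2), bool)))
        ).compressed
        np.testing.assert_allclose(h1, h2, atol=2e-2)

    def test_zero_intensity_falls_back_to_binary(self):
        m, _ = self._shape()
        h_zero = hu_moments(RoiSlice(np.zeros(m.shape), m)).compressed
        h_binary = hu_moments(RoiSlice(m.astype(float), m), gray_weighted=False).compressed
        np.testing.assert_allclose(h_zero, h_binary, atol=1e-12)


class TestSphericityDescriptors:
    def test_ball_esv_near_one(self, ball_roi):
        assert 0.9 <= esv(ball_roi) <= 1.1

    def test_cube_esv_analytic_limit(self, cube_roi):
        # side s cube: V = s^3, Feret = (s-1)*sqrt(3) between voxel centers
        assert esv(cube_roi) == pytest.approx(2 / (np.pi * np.sqrt(3)), abs=0.05)

    def test_rod_esv_tiny(self):
        mask = np.zeros((36, 5, 5), bool)
        mask[3:33, 2, 2] = True
        rod = RoiVolume(np.ones((36, 5, 5)), mask)
        assert esv(rod) < 0.01

    def test_ball_scdstd_small(self, ball_roi):
        assert scdstd(ball_roi) < 0.05

    def test_ellipsoid_scdstd_exceeds_ball(self):
        ball = make_roi(PhantomSpec(shape="ball", size=(8,), grid=(22, 22, 22)))
        ell = make_roi(PhantomSpec(shape="ellipsoid", size=(16, 8, 8), grid=(38, 22, 22)))
        assert scdstd(ell) > scdstd(ball)

    def test_single_voxel_degenerate_rules(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[2, 2, 2] = True
        roi = RoiVolume(np.ones((5, 5, 5)), mask)
        assert scdstd(roi) == 0.0
        assert ercld(roi) == 1.0

    def test_ercld_symmetric_rois(self, ball_roi, cube_roi):
        assert ercld(ball_roi) == pytest.approx(1.0, abs=1e-6)
        assert ercld(cube_roi) == pytest.approx(1.0, abs=1e-6)

    def test_ercld_hemisphere_above_one(self):
        # centroid of a hemisphere is displaced from its tight-box center
        roi = make_roi(PhantomSpec(shape="clipped_ball", size=(9,), grid=(26, 26, 26)))
        brute = _brute_ercld(roi)
        assert ercld(roi) > 1.0
        assert ercld(roi) == pytest.approx(brute, rel=1e-12)

    def test_esv_scdstd_monotone_on_stretch_ladder(self):
        """Stretching a ball into longer ellipsoids lowers ESV, raises SCDSTD."""
        e1s, e2s = [], []
        for stretch in (1.0, 1.3, 1.6, 2.0):
            roi = make_roi(
                PhantomSpec(shape="ellipsoid", size=(8 * stretch, 8, 8), grid=(48, 22, 22))
            )
            e1s.append(esv(roi))
            e2s.append(scdstd(roi))
        assert all(a > b for a, b in zip(e1s, e1s[1:]))
        assert all(a < b for a, b in zip(e2s, e2s[1:]))


def _brute_ercld(roi):
    """Independent oracle: direct enumeration of the 12 edge midpoints."""
    coords = np.argwhere(roi.mask)
    lo, hi = coords.min(0).astype(float), coords.max(0).astype(float)
    cen = coords.mean(0)
    box_c = (lo + hi) / 2
    mids = []
    for ax in range(3):
        for b1 in (0, 1):
            for b2 in (0, 1):
                m = box_c.copy()
                o = [a for a in range(3) if a != ax]
                m[o[0]] = (lo, hi)[b1][o[0]]
                m[o[1]] = (lo, hi)[b2][o[1]]
                mids.append(m)
    mids = np.array(mids)
    return np.linalg.norm(mids - cen, axis=1).mean() / np.linalg.norm(
        mids - box_c, axis=1
    ).mean()


class TestShapeBlock:
    def test_schema_and_key_slots(self, ball_roi):
        block = shape_feature_block(ball_roi)
        assert block.shape == (18,) and np.all(np.isfinite(block))
        assert 0.9 <= block[7] <= 1.1  # fs8 = ESV
        assert block[8] < 0.05  # fs9 = SCDSTD

    def test_translation_invariance_of_all_slots(self):
        rng = np.random.default_rng(5)
        small = make_roi(PhantomSpec(shape="blob", size=(5,), grid=(24, 24, 24), seed=9))
        img = np.full((40, 40, 40), 30.0)
        base = rng.uniform(0, 1, (24, 24, 24))
        blocks = []
        for dz, dy, dx in [(2, 3, 1), (12, 9, 14)]:
            m = np.zeros((40, 40, 40), bool)
            m[dz : dz + 24, dy : dy + 24, dx : dx + 24] = small.mask
            im = img.copy()
            im[dz : dz + 24, dy : dy + 24, dx : dx + 24] = small.intensities + base
            blocks.append(shape_feature_block(RoiVolume(im, m)))
        np.testing.assert_allclose(blocks[0], blocks[1], atol=1e-9)
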