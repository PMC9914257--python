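"""Unit and property tests for the frame-to-shrinkage pipeline."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from dryshrink import imaging
from dryshrink.errors import (
    DataError,
    DegenerateHistogramWarning,
    EmptyForegroundWarning,
    TieBreakWarning,
)


def disk_mask(shape, cy, cx, r):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


class TestToGrayscale:
    @pytest.mark.parametrize(
        "pixel, expected",
        [((60, 60, 60), 60), ((0, 0, 0), 0), ((10, 20, 31), 20), ((255, 255, 255), 255)],
    )
    def test_channel_mean(self, pixel, expected):
        img = np.array(pixel, dtype=np.uint8).reshape(1, 1, 3)
        assert imaging.to_grayscale(img)[0, 0] == expected

    def test_matches_exact_rational_mean(self, rng):
        img = rng.integers(0, 256, size=(31, 17, 3), dtype=np.uint8)
        got = imaging.to_grayscale(img)
        from fractions import Fraction

        for i, j in [(0, 0), (5, 11), (30, 16), (17, 3)]:
            mean = Fraction(int(img[i, j].astype(int).sum()), 3)
            # round half to even on the exact rational mean
            floor = mean.numerator // mean.denominator
            frac = mean - floor
            if frac > Fraction(1, 2) or (frac == Fraction(1, 2) and floor % 2 == 1):
                expected = floor + 1
            else:
                expected = floor
            assert got[i, j] == expected

    def test_rejects_non_rgb(self):
        with pytest.raises(DataError, match="3 channels"):
            imaging.to_grayscale(np.zeros((4, 4), dtype=np.uint8))
        with pytest.raises(DataError, match="3 channels"):
            imaging.to_grayscale(np.zeros((4, 4, 4), dtype=np.uint8))


class TestClusterThreshold:
    def test_two_spike_histogram(self):
        img = np.array([[50] * 8 + [200] * 8], dtype=np.uint8)
        assert imaging.cluster_threshold(img) == 125

    def test_constant_image_warns(self):
        img = np.full((5, 5), 100, dtype=np.uint8)
        with pytest.warns(DegenerateHistogramWarning):
            assert imaging.cluster_threshold(img) == 100

    def test_fixed_point_matches_brute_force(self, rng):
        """The returned integer satisfies T = floor((m_lo + m_hi)/2) exactly,
        as found by scanning all 256 candidate thresholds."""
        img = np.concatenate(
            [
                rng.normal(60, 12, 600).clip(0, 255),
                rng.normal(190, 20, 400).clip(0, 255),
            ]
        ).astype(np.uint8)
        levels = img.astype(float)
        fixed_points = []
        for t in range(256):
            lo, hi = levels[levels <= t], levels[levels > t]
            if lo.size and hi.size:
                if int((lo.mean() + hi.mean()) // 2) == t:
                    fixed_points.append(t)
        got = imaging.cluster_threshold(img.reshape(40, 25))
        assert got in fixed_points

    def test_otsu_variant_selectable(self, rng):
        from skimage.filters import threshold_otsu

        img = np.concatenate(
            [rng.normal(60, 12, 600), rng.normal(190, 20, 400)]
        ).clip(0, 255).astype(np.uint8).reshape(40, 25)
        assert imaging.cluster_threshold(img, method="otsu") == int(threshold_otsu(img))


class TestBinarize:
    def test_all_above(self):
        img = np.full((3, 3), 200, dtype=np.uint8)
        assert imaging.binarize(img, 125).all()

    def test_boundary_is_strict(self):
        img = np.full((3, 3), 200, dtype=np.uint8)
        assert not imaging.binarize(img, 200).any()

    def test_checkerboard(self):
        img = np.where(np.indices((6, 6)).sum(axis=0) % 2 == 0, 200, 50).astype(np.uint8)
        mask = imaging.binarize(img, 125)
        assert (mask == (img == 200)).all()

    def test_dark_foreground(self):
        img = np.array([[10, 240]], dtype=np.uint8)
        assert imaging.binarize(img, 125, bright_foreground=False).tolist() == [[True, False]]


def flood_fill_oracle(mask):
    """Complement of a BFS flood fill (4-connectivity) from border background."""
    from collections import deque

    h, w = mask.shape
    outside = np.zeros_like(mask, dtype=bool)
    queue = deque()
    for i in range(h):
        for j in (0, w - 1):
            if not mask[i, j] and not outside[i, j]:
                outside[i, j] = True
                queue.append((i, j))
    for j in range(w):
        for i in (0, h - 1):
            if not mask[i, j] and not outside[i, j]:
                outside[i, j] = True
                queue.append((i, j))
    while queue:
        i, j = queue.popleft()
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            ni, nj = i + di, j + dj
            if 0 <= ni < h and 0 <= nj < w and not mask[ni, nj] and not outside[ni, nj]:
                outside[ni, nj] = True
                queue.append((ni, nj))
    return ~outside


class TestFillHoles:
    def test_annulus_becomes_solid(self):
        outer = disk_mask((21, 21), 10, 10, 8)
        inner = disk_mask((21, 21), 10, 10, 4)
        filled = imaging.fill_holes(outer & ~inner)
        assert (filled == outer).all()

    def test_no_holes_unchanged(self):
        mask = disk_mask((15, 15), 7, 7, 5)
        assert (imaging.fill_holes(mask) == mask).all()

    @given(
        hnp.arrays(bool, hnp.array_shapes(min_dims=2, max_dims=2, min_side=2, max_side=12))
    )
    def test_matches_flood_fill_oracle(self, mask):
        assert (imaging.fill_holes(mask) == flood_fill_oracle(mask)).all()

    @given(
        hnp.arrays(bool, hnp.array_shapes(min_dims=2, max_dims=2, min_side=2, max_side=12))
    )
    def test_idempotent_and_monotone(self, mask):
        once = imaging.fill_holes(mask)
        assert (imaging.fill_holes(once) == once).all()
        assert (once | mask == once).all()  # foreground never removed


class TestFilterTopParticles:
    def make_disks(self, radii):
        mask = np.zeros((60, 40 * len(radii)), dtype=bool)
        for i, r in enumerate(radii):
            mask |= disk_mask(mask.shape, 30, 20 + 40 * i, r)
        return mask

    def test_keeps_k_largest(self):
        radii = [3, 5, 7, 9, 11, 13, 15, 17]
        mask = self.make_disks(radii)
        ps = imaging.filter_top_particles(mask, k=6)
        assert len(ps) == 6
        smallest_kept = sorted(ps.areas)[0]
        dropped = disk_mask(mask.shape, 30, 20, 3).sum()
        assert smallest_kept > dropped

    def test_fewer_than_k(self):
        mask = self.make_disks([4, 6, 8, 10])
        ps = imaging.filter_top_particles(mask, k=6)
        assert len(ps) == 4

    def test_tie_at_rank_k_keeps_earlier_label(self):
        mask = np.zeros((10, 30), dtype=bool)
        mask[1:3, 1:3] = True  # area 4, first in raster order
        mask[5:8, 5:9] = True  # area 12
        mask[6:8, 20:22] = True  # area 4, later in raster order
        with pytest.warns(TieBreakWarning):
            ps = imaging.filter_top_particles(mask, k=2)
        kept = ps.mask(mask.shape)
        assert kept[1, 1] and kept[5, 5] and not kept[6, 20]

    def test_empty_mask_warns(self):
        with pytest.warns(EmptyForegroundWarning):
            ps = imaging.filter_top_particles(np.zeros((5, 5), dtype=bool))
        assert len(ps) == 0 and imaging.total_area(ps) == 0

    def test_subset_of_input(self, rng):
        mask = rng.random((40, 40)) > 0.6
        ps = imaging.filter_top_particles(mask, k=3)
        assert len(ps) <= 3
        assert not (ps.mask(mask.shape) & ~mask).any()


class TestTotalArea:
    def test_sums_component_areas(self):
        mask = np.zeros((20, 60), dtype=bool)
        mask[2:12, 2:12] = True  # 100
        mask[2:7, 20:30] = True  # 50
        mask[2:7, 40:45] = True  # 25
        ps = imaging.filter_top_particles(mask, k=6)
        assert imaging.total_area(ps) == 175

    def test_disk_area_near_analytic(self):
        mask = disk_mask((60, 60), 30, 30, 20)
        ps = imaging.filter_top_particles(mask, k=1)
        assert imaging.total_area(ps) == pytest.approx(np.pi * 400, rel=0.02)


class TestShrinkageSeries:
    def test_ratio(self):
        ss = imaging.shrinkage_series([100, 80, 60], [0.0, 0.5, 1.0])
        assert ss.shrinkage.tolist() == [1.0, 0.8, 0.6]

    def test_constant(self):
        ss = imaging.shrinkage_series([70, 70], [0, 1])
        assert (ss.shrinkage == 1).all()

    def test_direct_division(self):
        assert imaging.shrinkage_series([200, 150], [0, 1]).shrinkage.tolist() == [1.0, 0.75]

    def test_errors(self):
        with pytest.raises(DataError, match="zero"):
            imaging.shrinkage_series([0, 10], [0, 1])
        with pytest.raises(DataError, match="egative"):
            imaging.shrinkage_series([10, -1], [0, 1])
        with pytest.raises(DataError, match="length"):
            imaging.shrinkage_series([10, 5], [0.0])


def test_translation_equivariance(rng):
    """Shifting the whole scene by an integer offset leaves total area unchanged."""
    frame = np.full((80, 90), 30, dtype=np.uint8)
    for cy, cx, r in [(20, 20, 9), (20, 60, 7), (55, 30, 11)]:
        frame[disk_mask(frame.shape, cy, cx, r)] = 220
    shifted = np.roll(frame, (7, -5), axis=(0, 1))
    a0, _ = imaging.process_frame(frame, top_k=3)
    a1, _ = imaging.process_frame(shifted, top_k=3)
    assert a0 == a1
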