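"""Patch sampling, overlap constraints and block-histogram descriptors."""

import numpy as np
import pytest

from ehmax.config import default_band_table
from ehmax.exceptions import ParameterError, SizeError
from ehmax.patches import (color_block_histogram, color_histogram_field,
                           describe_patch, descriptor_field, extract_patch,
                           footprint_rect, sample_patch_centers,
                           select_points_greedy)

BAND1 = default_band_table()[0]


def _greedy_oracle(points, min_dist, max_count):
    kept = []
    for x, y in points:
        if len(kept) >= max_count:
            break
        if all(np.hypot(x - kx, y - ky) >= min_dist for kx, ky in kept):
            kept.append((x, y))
    return kept


class TestGreedySelection:
    def test_hand_worked_example(self):
        kept = select_points_greedy([(0, 0), (1, 1), (10, 10)], min_dist=4)
        assert kept == [(0.0, 0.0), (10.0, 10.0)]

    def test_tiny_min_dist_keeps_everything(self):
        pts = [(i, j) for i in range(5) for j in range(5)]
        assert len(select_points_greedy(pts, min_dist=0.5)) == 25

    def test_matches_quadratic_oracle(self, rng):
        pts = [tuple(p) for p in rng.uniform(0, 50, size=(200, 2))]
        got = select_points_greedy(pts, min_dist=7.0, max_count=40)
        assert got == _greedy_oracle(pts, 7.0, 40)

    def test_prefix_property(self, rng):
        """Points after the kept set fills up cannot change the selection."""
        pts = [tuple(p) for p in rng.uniform(0, 30, size=(80, 2))]
        full = select_points_greedy(pts, min_dist=5.0, max_count=10)
        truncated = select_points_greedy(pts + [(0.1, 0.1)] * 50,
                                         min_dist=5.0, max_count=10)
        assert full == truncated

    def test_nonpositive_min_dist_rejected(self):
        with pytest.raises(ParameterError):
            select_points_greedy([(0, 0)], min_dist=0.0)


class TestSampleCenters:
    def test_centers_respect_quarter_patch_distance(self, rng):
        centers = sample_patch_centers((31, 31), 16, max_count=30, rng=rng)
        for i in range(len(centers)):
            for j in range(i + 1, len(centers)):
                d = np.hypot(centers[i][0] - centers[j][0],
                             centers[i][1] - centers[j][1])
                assert d >= 4.0

    def test_salient_hotspot_becomes_first_center(self):
        pts = np.array([[15, 12], [15, 13], [20, 20]])
        centers = sample_patch_centers((31, 31), 16, max_count=5,
                                       sorted_points=pts)
        assert centers[0] == (15, 12)

    def test_same_seed_gives_identical_random_centers(self):
        a = sample_patch_centers((31, 31), 16, 10, rng=np.random.default_rng(5))
        b = sample_patch_centers((31, 31), 16, 10, rng=np.random.default_rng(5))
        assert a == b

    def test_footprints_stay_inside_grid(self, rng):
        for cx, cy in sample_patch_centers((31, 31), 16, 30, rng=rng):
            assert 0 <= cx - 8 and cx + 8 <= 31
            assert 0 <= cy - 8 and cy + 8 <= 31

    def test_out_of_range_salient_points_are_clipped_inside(self):
        pts = np.array([[0, 0], [30, 30]])
        centers = sample_patch_centers((31, 31), 16, 5, sorted_points=pts)
        assert centers[0] == (8, 8)
        assert centers[1] == (23, 23)


class TestDescriptor:
    def test_orientation_descriptor_length_is_nine_blocks(self, rng):
        d = describe_patch(rng.random((16, 16, 12)))
        assert d.vector.shape == (108,)
        d28 = describe_patch(rng.random((28, 28, 12)))
        assert d28.vector.shape == (108,)

    def test_zero_patch_gives_zero_descriptor(self):
        d = describe_patch(np.zeros((16, 16, 12)))
        assert np.allclose(d.vector, 0.0)

    def test_single_orientation_energy_yields_basis_blocks(self, rng):
        t = np.zeros((16, 16, 12))
        t[:, :, 7] = rng.random((16, 16)) + 0.1
        d = describe_patch(t)
        blocks = d.vector.reshape(9, 12)
        for b in blocks:
            assert np.allclose(b, np.eye(12)[7], atol=1e-12)

    def test_descriptor_invariant_to_patch_scaling(self, rng):
        t = rng.random((16, 16, 12))
        a = describe_patch(t).vector
        b = describe_patch(17.3 * t).vector
        assert np.allclose(a, b, atol=1e-12)

    def test_blocks_tile_the_patch_exactly(self):
        # offsets 0, n/4, n/2 with side n/2 span [0, n) in each axis
        for n in (16, 28):
            assert 2 * (n // 4) + n // 2 == n

    def test_block_sums_match_hand_computed_histogram(self, rng):
        t = rng.random((16, 16, 3))
        d = describe_patch(t).vector.reshape(9, 3)
        k = 0
        for by in (0, 4, 8):
            for bx in (0, 4, 8):
                h = t[by:by + 8, bx:bx + 8, :].sum(axis=(0, 1))
                h = h / np.linalg.norm(h)
                assert np.allclose(d[k], h, atol=1e-12)
                k += 1

    def test_non_multiple_of_four_size_rejected(self, rng):
        with pytest.raises(ParameterError):
            describe_patch(rng.random((10, 10, 4)))


class TestDescriptorField:
    def test_field_matches_per_patch_descriptors(self, rng):
        stack = rng.random((24, 26, 5))
        field = descriptor_field(stack, 16)
        assert field.shape == (9, 11, 45)
        for r in (0, 4, 8):
            for c in (0, 5, 10):
                naive = describe_patch(stack[r:r + 16, c:c + 16, :]).vector
                assert np.allclose(field[r, c], naive, atol=1e-9)

    def test_grid_too_small_rejected(self, rng):
        with pytest.raises(SizeError):
            descriptor_field(rng.random((10, 10, 4)), 16)


class TestColorHistogram:
    def test_block_layout_and_length(self, rng):
        crop = rng.integers(0, 256, (68, 68, 3), dtype=np.uint8)
        v = color_block_histogram(crop, bins=8)
        assert v.shape == (96,)
        for block in v.reshape(4, 24):
            assert np.linalg.norm(block) == pytest.approx(1.0)

    def test_field_matches_naive_crops(self, rng):
        rgb = rng.integers(0, 256, (128, 128, 3), dtype=np.uint8)
        field = color_histogram_field(rgb, BAND1, 16, (31, 31))
        assert field.shape == (16, 16, 96)
        for tl in ((0, 0), (7, 3), (15, 15)):
            center = (tl[1] + 8, tl[0] + 8)
            y0, y1, x0, x1 = footprint_rect(center, 16, BAND1)
            naive = color_block_histogram(rgb[y0:y1, x0:x1])
            assert np.allclose(field[tl[0], tl[1]], naive, atol=1e-9)


class TestExtractPatch:
    def test_footprint_rect_covers_member_windows(self):
        y0, y1, x0, x1 = footprint_rect((8, 8), 16, BAND1)
        assert (y0, x0) == (0, 0)
        assert (y1, x1) == (15 * 4 + 8, 15 * 4 + 8)

    def test_out_of_grid_patch_rejected(self, rng):
        with pytest.raises(SizeError):
            extract_patch(rng.random((31, 31, 4)), (2, 2), 16)
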