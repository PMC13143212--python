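"""Thresholding, Hoshen–Kopelman labeling, peeling, spine extraction and
the head/neck split, each against an independent oracle where one exists."""

import numpy as np
import pytest
from scipy import ndimage as ndi

import spinemetrics as sm
from spinemetrics.benchmark import flood_fill_label, partitions_equal
from spinemetrics.images import BinaryMask, GrayscaleImage
from spinemetrics.segmentation import (PeelRecord, auto_peel_depth, peel,
                                       reconstruct, resolve_threshold)

PX = 0.1


class TestBinarize:
    @pytest.mark.parametrize("values,thr,expected", [
        ([[0.1, 0.9]], 0.5, [[False, True]]),
        ([[0.1, 0.9]], 1.0, [[False, False]]),       # above max -> all false
        ([[0.1, 0.9]], 0.1, [[True, True]]),         # >= convention at min
    ])
    def test_threshold_convention(self, values, thr, expected):
        mask = sm.binarize(GrayscaleImage(np.array(values), PX), thr)
        assert mask.values.tolist() == expected
        assert mask.pixel_size == PX

    def test_nonfinite_threshold_rejected(self):
        img = GrayscaleImage(np.ones((2, 2)), PX)
        with pytest.raises(ValueError):
            sm.binarize(img, np.nan)

    def test_mean_plus_ksd_spec_string(self):
        img = GrayscaleImage(np.array([[0.0, 2.0], [0.0, 2.0]]), PX)
        assert resolve_threshold(img, "mean+2*sd") == pytest.approx(3.0)
        assert resolve_threshold(img, 0.7) == 0.7


class TestHoshenKopelman:
    def test_diagonal_pixels_split_under_4_connectivity(self):
        mask = BinaryMask(np.eye(2, dtype=bool), PX)
        assert sm.label_clusters(mask, 4).n_islands == 2
        assert sm.label_clusters(mask, 8).n_islands == 1

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_flood_fill_on_random_masks(self, connectivity):
        rng = np.random.default_rng(42)
        for _ in range(100):
            m = rng.random((32, 32)) < 0.4
            ours = sm.label_clusters(BinaryMask(m, PX), connectivity).labels
            assert partitions_equal(ours, flood_fill_label(m, connectivity))

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_scipy_label(self, connectivity):
        rng = np.random.default_rng(7)
        struct = ndi.generate_binary_structure(2, 1 if connectivity == 4 else 2)
        for _ in range(50):
            m = rng.random((24, 24)) < 0.45
            ours = sm.label_clusters(BinaryMask(m, PX), connectivity).labels
            ref, _ = ndi.label(m, structure=struct)
            assert partitions_equal(ours, ref)

    def test_island_sizes_sum_to_foreground(self):
        rng = np.random.default_rng(3)
        m = rng.random((20, 20)) < 0.5
        lm = sm.label_clusters(BinaryMask(m, PX), 8)
        assert sum(lm.island_sizes.values()) == m.sum()
        assert sorted(lm.island_sizes) == list(range(1, lm.n_islands + 1))


class TestRemoveSmallIslands:
    def test_keeps_only_large_islands(self):
        m = np.zeros((10, 10), dtype=bool)
        m[0, 0:5] = True          # size 5
        m[5, 0:2] = True          # size 2
        m[9, 9] = True            # size 1
        lm = sm.label_clusters(BinaryMask(m, PX), 8)
        kept = sm.remove_small_islands(lm, 3)
        assert kept.area_px == 5
        assert kept.values[0, 0:5].all()

    def test_min_area_one_is_identity(self):
        rng = np.random.default_rng(0)
        m = rng.random((16, 16)) < 0.3
        lm = sm.label_clusters(BinaryMask(m, PX), 8)
        assert np.array_equal(sm.remove_small_islands(lm, 1).values, m)

    def test_matches_flood_fill_filter_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            m = rng.random((24, 24)) < 0.4
            lm = sm.label_clusters(BinaryMask(m, PX), 8)
            kept = sm.remove_small_islands(lm, 4)
            ref = flood_fill_label(m, 8)
            expect = np.zeros_like(m)
            for lab in range(1, ref.max() + 1):
                if (ref == lab).sum() >= 4:
                    expect |= ref == lab
            assert np.array_equal(kept.values, expect)


class TestPeel:
    def test_single_pixel_removed_first_iteration(self):
        m = np.zeros((5, 5), dtype=bool)
        m[2, 2] = True
        rec = peel(BinaryMask(m, PX), 3)
        assert rec.depth_map[2, 2] == 1
        assert not rec.core_mask(BinaryMask(m, PX)).values.any()

    def test_three_wide_ribbon_leaves_center_line(self):
        m = np.zeros((7, 20), dtype=bool)
        m[2:5, :] = True
        rec = peel(BinaryMask(m, PX), 1)
        core = rec.core_mask(BinaryMask(m, PX)).values
        # manual erosion oracle: only the middle row survives (minus the
        # column ends, which border background)
        assert core[3, 1:19].all()
        assert not core[2].any() and not core[4].any()

    @pytest.mark.parametrize("radius", [4, 6, 9])
    def test_disk_max_depth_equals_radius(self, radius):
        yy, xx = np.mgrid[0:32, 0:32]
        disk = (yy - 16) ** 2 + (xx - 16) ** 2 <= radius**2
        rec = peel(BinaryMask(disk, PX), radius + 5)
        # distance-transform oracle: peeling strips one border layer per
        # iteration, so the survival depth equals the interior depth
        assert abs(rec.depth_map.max() - radius) <= 1

    def test_reconstruction_is_conservative(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            m = ndi.binary_dilation(rng.random((32, 32)) < 0.1)
            seed = ndi.binary_erosion(m)
            out = reconstruct(seed, m, 3)
            assert not (out & ~m).any()


class TestSpineExtraction:
    def test_single_mushroom_spine_isolated(self, one_spine_spec):
        from conftest import segment_noiseless
        mask, seg, truth = segment_noiseless(one_spine_spec)
        assert seg.n_spines == 1
        island = seg.spine_islands.mask_of(1)
        true_island = truth.spine_masks[0]
        inter = (island.values & true_island.values).sum()
        assert inter / true_island.area_px > 0.6  # head+neck recovered
        # channel within a 1-px ring of truth
        diff = seg.channel_mask.values ^ truth.channel_mask.values
        eroded_truth = ndi.binary_erosion(truth.channel_mask.values, iterations=2)
        assert not (diff & eroded_truth).any()

    def test_no_spines_yields_empty_islands_and_full_channel(self, one_spine_spec):
        from dataclasses import replace
        from conftest import segment_noiseless
        spec = replace(one_spine_spec, spines=())
        mask, seg, truth = segment_noiseless(spec)
        assert seg.n_spines == 0
        coverage = (seg.channel_mask.values & mask.values).sum() / mask.area_px
        assert coverage >= 0.95

    def test_two_spines_opposite_sides(self, one_spine_spec):
        from dataclasses import replace
        from conftest import segment_noiseless
        spines = (
            sm.SpineSpec(anchor=(48.0, 40.0), side=-1, neck_length_um=0.5,
                         neck_width_um=0.3, head_diameter_um=0.6),
            sm.SpineSpec(anchor=(48.0, 88.0), side=+1, neck_length_um=0.5,
                         neck_width_um=0.3, head_diameter_um=0.6),
        )
        spec = replace(one_spine_spec, spines=spines)
        _, seg, _ = segment_noiseless(spec)
        assert seg.n_spines == 2

    def test_partition_invariant(self, one_spine_spec):
        """Channel and spine islands are disjoint and lie in the input mask."""
        from conftest import segment_noiseless
        mask, seg, _ = segment_noiseless(one_spine_spec)
        chan = seg.channel_mask.values
        spines = seg.spine_islands.labels > 0
        assert not (chan & spines).any()
        assert not ((chan | spines) & ~mask.values).any()

    def test_peel_depth_exceeding_width_raises(self):
        m = np.zeros((10, 30), dtype=bool)
        m[4:6, :] = True   # 2 px wide: depth-2 peel empties it
        with pytest.raises(ValueError, match="peel depth"):
            sm.extract_spines_by_peeling(BinaryMask(m, PX), 2, 4)

    def test_auto_peel_depth_on_tube(self, straight_tube_mask):
        depth = auto_peel_depth(straight_tube_mask)
        assert 1 <= depth <= 3


class TestCenterline:
    def test_straight_ribbon_middle_row_and_length(self, straight_tube_mask):
        cl = sm.extract_centerline(straight_tube_mask, 4)
        rows = {r for r, _ in cl.path}
        assert rows <= {19, 20, 21}           # middle row of rows 17..23
        assert cl.length_px == pytest.approx(99, abs=4)

    def test_l_shaped_tube_passes_both_arm_midlines(self):
        m = np.zeros((100, 100), dtype=bool)
        m[17:24, 17:80] = True
        m[17:80, 17:24] = True
        cl = sm.extract_centerline(BinaryMask(m, PX), 4)
        path = np.asarray(cl.path)
        horiz = path[path[:, 1] > 35]
        vert = path[path[:, 0] > 35]
        assert np.abs(horiz[:, 0] - 20).max() <= 1
        assert np.abs(vert[:, 1] - 20).max() <= 1

    def test_annulus_raises_unless_closed_allowed(self):
        yy, xx = np.mgrid[0:64, 0:64]
        rr = np.hypot(yy - 32, xx - 32)
        ann = (rr >= 12) & (rr <= 15)
        with pytest.raises(ValueError, match="closed"):
            sm.extract_centerline(BinaryMask(ann, PX), 2)
        cl = sm.extract_centerline(BinaryMask(ann, PX), 2, allow_closed=True)
        assert cl.closed
        assert cl.length_px == pytest.approx(2 * np.pi * 13.5, rel=0.1)

    def test_centerline_method_no_spines_empty_residual(self, straight_tube_mask):
        cl = sm.extract_centerline(straight_tube_mask, 4)
        seg = sm.extract_spines_by_centerline(straight_tube_mask, cl, 4)
        assert seg.n_spines == 0

    def test_zero_layers_residual_is_mask_minus_centerline(self, straight_tube_mask):
        cl = sm.extract_centerline(straight_tube_mask, 4)
        seg = sm.extract_spines_by_centerline(straight_tube_mask, cl, 0,
                                              min_head_area=1)
        expected = straight_tube_mask.values & ~cl.raster(straight_tube_mask.shape)
        assert np.array_equal(seg.spine_islands.labels > 0, expected)


class TestCompareMethods:
    def test_identical_results_all_jaccard_one(self, one_spine_spec):
        from conftest import segment_noiseless
        _, seg, _ = segment_noiseless(one_spine_spec)
        comp = sm.compare_methods(seg, seg)
        assert comp.matches and all(j == 1.0 for _, _, j in comp.matches)

    def test_disjoint_results_no_matches(self):
        a = np.zeros((10, 10), dtype=np.int64)
        b = np.zeros((10, 10), dtype=np.int64)
        a[1, 1] = 1
        b[8, 8] = 1
        from spinemetrics.images import LabelMap
        from spinemetrics.segmentation import SegmentationResult
        empty = BinaryMask(np.zeros((10, 10), bool), PX)
        ra = SegmentationResult(empty, LabelMap(a, pixel_size=PX), "peel")
        rb = SegmentationResult(empty, LabelMap(b, pixel_size=PX), "centerline")
        comp = sm.compare_methods(ra, rb)
        assert not comp.matches
        assert comp.unmatched_a == [1] and comp.unmatched_b == [1]

    def test_jaccard_matches_pairwise_overlap_oracle(self, one_spine_spec):
        from conftest import segment_noiseless
        mask, seg, _ = segment_noiseless(one_spine_spec)
        cl = sm.extract_centerline(mask, 4)
        seg2 = sm.extract_spines_by_centerline(mask, cl, 5, 10)
        comp = sm.compare_methods(seg, seg2)
        for la, lb, j in comp.matches:
            ma = seg.spine_islands.labels == la
            mb = seg2.spine_islands.labels == lb
            assert j == pytest.approx((ma & mb).sum() / (ma | mb).sum())


class TestSplitHeadNeck:
    def test_mushroom_head_recovered(self, mushroom_island):
        head, neck = sm.split_head_neck(mushroom_island, max_neck_width_px=2)
        yy, xx = np.mgrid[0:24, 0:16]
        true_head = (yy - 7) ** 2 + (xx - 8) ** 2 <= 3.0**2
        recovered = (head.values & true_head).sum() / true_head.sum()
        assert recovered >= 0.85
        # no neck pixels beyond a 1-px ring below the head
        assert not head.values[12:, :].any()
        assert neck.values[12:18, 7:9].any()

    def test_stubby_spine_is_all_head(self):
        yy, xx = np.mgrid[0:16, 0:16]
        blob = (yy - 8) ** 2 + (xx - 8) ** 2 <= 4.0**2
        island = BinaryMask(blob, PX)
        head, neck = sm.split_head_neck(island, max_neck_width_px=3)
        assert neck.area_px == 0
        assert np.array_equal(head.values, blob)

    def test_thin_spine_is_all_neck(self):
        m = np.zeros((20, 8), dtype=bool)
        m[2:18, 3:5] = True   # uniform 2-px-wide strip
        island = BinaryMask(m, PX)
        head, neck = sm.split_head_neck(island, max_neck_width_px=3)
        assert head.area_px == 0
        assert np.array_equal(neck.values, m)

    def test_head_neck_partition_island(self, mushroom_island):
        head, neck = sm.split_head_neck(mushroom_island, max_neck_width_px=2)
        assert not (head.values & neck.values).any()
        assert np.array_equal(head.values | neck.values, mushroom_island.values)
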