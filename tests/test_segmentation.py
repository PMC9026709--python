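import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from skimage import measure

from sepatrack.core_io import LabelMap, PipelineConfig
from sepatrack.segmentation import (BodyRegions, assign_regions,
                                    correct_body_overlap, find_edge_regions,
                                    segment_frame, watershed_fill)
from sepatrack.synthdata import render_aGT, synthetic_bodies


class TestFindEdgeRegions:
    def test_vertical_line_splits_rectangle(self):
        F = np.zeros((40, 60), bool); F[5:35, 5:55] = True
        G = np.zeros((40, 60)); G[5:35, 30] = 200
        er = find_edge_regions(G, F, 60)
        assert er.L == 2
        left = er.regions[20, 10]
        right = er.regions[20, 50]
        assert left > 0 and right > 0 and left != right

    def test_subthreshold_edges_single_region(self):
        F = np.zeros((40, 60), bool); F[5:35, 5:55] = True
        G = np.full((40, 60), 59.0)
        er = find_edge_regions(G, F, 60)
        assert er.L == 1
        assert np.array_equal(er.regions > 0, F)

    def test_exact_threshold_excluded(self):
        F = np.zeros((40, 60), bool); F[5:35, 5:55] = True
        G = np.zeros((40, 60)); G[5:35, 30] = 60.0  # exactly theta: not an edge
        er = find_edge_regions(G, F, 60)
        assert er.L == 1

    def test_empty_foreground(self):
        er = find_edge_regions(np.zeros((32, 32)), np.zeros((32, 32), bool), 60)
        assert er.L == 0

    def test_regions_sorted_by_area(self):
        F = np.zeros((40, 60), bool); F[5:35, 5:55] = True
        G = np.zeros((40, 60)); G[5:35, 40] = 200  # uneven split
        er = find_edge_regions(G, F, 60)
        areas = [(er.regions == i).sum() for i in range(1, er.L + 1)]
        assert areas == sorted(areas, reverse=True)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 10 ** 6))
    def test_area_conservation(self, seed):
        rng = np.random.default_rng(seed)
        F = rng.random((32, 32)) < 0.6
        G = rng.random((32, 32)) * 255
        er = find_edge_regions(G, F, 60)
        region_area = int((er.regions > 0).sum())
        midline_area = int(er.midline.pixels.sum())
        assert region_area + midline_area == int(F.sum())


class TestCorrectBodyOverlap:
    def test_disjoint_unchanged(self):
        a = np.zeros((20, 30), bool); a[5:15, 2:10] = True
        b = np.zeros((20, 30), bool); b[5:15, 15:25] = True
        oa, ob = correct_body_overlap(a, b)
        assert np.array_equal(oa.pixels, a) and np.array_equal(ob.pixels, b)

    def test_band_split_at_midline_with_tie_to_first(self):
        # two 10x10 squares overlapping in a 10x5 band; the equidistant
        # column goes to the first body
        a = np.zeros((20, 30), bool); a[5:15, 0:10] = True    # centroid col 4.5
        b = np.zeros((20, 30), bool); b[5:15, 5:15] = True    # centroid col 9.5
        oa, ob = correct_body_overlap(a, b)
        assert not (oa.pixels & ob.pixels).any()
        assert np.array_equal(oa.pixels | ob.pixels, a | b)
        assert oa.pixels[10, 7] and not ob.pixels[10, 7]  # tie column -> A
        assert oa.pixels[10, 6] and ob.pixels[10, 8]

    def test_identical_bodies_all_to_first(self):
        a = np.zeros((20, 20), bool); a[5:15, 5:15] = True
        oa, ob = correct_body_overlap(a, a.copy())
        assert np.array_equal(oa.pixels, a)
        assert not ob.pixels.any()

    def test_empty_body_passthrough(self):
        a = np.zeros((20, 20), bool); a[5:15, 5:15] = True
        oa, ob = correct_body_overlap(a, np.zeros((20, 20), bool))
        assert np.array_equal(oa.pixels, a) and not ob.pixels.any()

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10 ** 6))
    def test_disjoint_union_preserved(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random((16, 16)) < 0.4
        b = rng.random((16, 16)) < 0.4
        if not a.any() or not b.any():
            return
        oa, ob = correct_body_overlap(a, b)
        assert not (oa.pixels & ob.pixels).any()
        assert np.array_equal(oa.pixels | ob.pixels, a | b)


def _two_region_edges(area1=130, area2=110):
    """EdgeRegions with two rectangular regions of given areas."""
    F = np.zeros((40, 60), bool)
    R = np.zeros((40, 60), np.int32)
    R[5:18, 5:15] = 1   # 13x10 = 130
    R[25:36, 30:40] = 2  # 11x10 = 110
    F |= R > 0
    from sepatrack.segmentation import EdgeRegions
    from sepatrack.core_io import BinaryMask
    return EdgeRegions(regions=R, L=2,
                       midline=BinaryMask(np.zeros((40, 60), bool), "boundary"))


class TestAssignRegions:
    def test_two_bodies_one_region_each(self):
        er = _two_region_edges()
        b1 = np.zeros((40, 60), bool); b1[6:12, 6:12] = True
        b2 = np.zeros((40, 60), bool); b2[26:32, 31:37] = True
        m = assign_regions(er, BodyRegions(masks=[b1, b2]))
        assert not m.unseparated
        # group areas: 130 (region1 u body1) vs 110 -> labels 1 and 2
        assert m.labels[10, 10] == 1 and m.labels[30, 35] == 2

    def test_single_body_over_both_regions_ignored(self):
        er = _two_region_edges()
        body = np.zeros((40, 60), bool)
        body[6:12, 6:12] = True
        body[26:32, 31:37] = True  # one detector blob claiming both regions
        m = assign_regions(er, BodyRegions(masks=[body]))
        assert not m.unseparated
        assert m.labels[10, 10] == 1 and m.labels[30, 35] == 2

    def test_no_bodies_size_ordering(self):
        er = _two_region_edges()
        m = assign_regions(er, None)
        assert m.labels[10, 10] == 1  # bigger region -> label 1
        assert m.labels[30, 35] == 2

    def test_conflicting_union_pixels_become_background(self):
        # body 2 spills into region 1 (which belongs to body 1): the
        # doubly-claimed pixels must fall back to background
        er = _two_region_edges()
        b1 = np.zeros((40, 60), bool); b1[6:14, 6:13] = True
        b2 = np.zeros((40, 60), bool); b2[26:34, 31:38] = True
        spill = np.zeros((40, 60), bool); spill[16, 6:9] = True  # inside region 1
        b2 |= spill
        m = assign_regions(er, BodyRegions(masks=[b1, b2]))
        assert (m.labels[spill] == 0).all()
        assert m.labels[10, 10] == 1 and m.labels[30, 35] == 2

    def test_single_region_flagged(self):
        from sepatrack.segmentation import EdgeRegions
        from sepatrack.core_io import BinaryMask
        R = np.zeros((30, 30), np.int32); R[5:25, 5:25] = 1
        er = EdgeRegions(regions=R, L=1,
                         midline=BinaryMask(np.zeros((30, 30), bool), "boundary"))
        m = assign_regions(er, None)
        assert m.unseparated


class TestWatershedFill:
    def test_markers_tiling_foreground_idempotent(self):
        F = np.zeros((30, 40), bool); F[5:25, 5:35] = True
        mk = np.zeros((30, 40), np.uint8)
        mk[5:25, 5:20] = 1
        mk[5:25, 20:35] = 2
        out = watershed_fill(LabelMap(mk), F, np.zeros((30, 40)))
        assert np.array_equal(out.labels, mk)

    def test_ridge_splits_evenly(self):
        F = np.zeros((30, 40), bool); F[5:25, 5:35] = True
        G = np.zeros((30, 40)); G[5:25, 20] = 200
        mk = np.zeros((30, 40), np.uint8)
        mk[15, 10] = 1
        mk[15, 30] = 2
        out = watershed_fill(LabelMap(mk), F, G)
        a1 = (out.labels == 1).sum()
        a2 = (out.labels == 2).sum()
        assert abs(a1 - a2) <= 2 * 20  # within the ridge width
        assert np.array_equal(out.labels > 0, F)

    def test_single_marker_fills_everything(self):
        F = np.zeros((30, 40), bool); F[5:25, 5:35] = True
        mk = np.zeros((30, 40), np.uint8); mk[15, 10] = 1
        out = watershed_fill(LabelMap(mk), F, np.zeros((30, 40)))
        assert (out.labels[F] == 1).all()
        assert out.unseparated

    def test_no_markers_flagged(self):
        F = np.zeros((30, 40), bool); F[5:25, 5:35] = True
        out = watershed_fill(LabelMap(np.zeros((30, 40), np.uint8)), F,
                             np.zeros((30, 40)))
        assert out.unseparated and not out.labels.any()

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10 ** 6))
    def test_labels_exactly_tile_foreground(self, seed):
        rng = np.random.default_rng(seed)
        F = rng.random((24, 24)) < 0.6
        if not F.any():
            return
        mk = np.zeros((24, 24), np.uint8)
        fg = np.argwhere(F)
        idx = rng.choice(len(fg), size=min(4, len(fg)), replace=False)
        for k, (r, c) in enumerate(fg[idx]):
            mk[r, c] = 1 + (k % 2)
        out = watershed_fill(LabelMap(mk), F, rng.random((24, 24)) * 255)
        assert np.array_equal(out.labels > 0, F)
        # markers preserved verbatim
        assert (out.labels[mk > 0] == mk[mk > 0]).all()


class TestSegmentFrame:
    def test_disjoint_instances_direct_labels(self, short_sequence, cfg):
        frames, gts, upper = short_sequence
        t = int(np.nonzero(upper == 0)[0][0])
        F = gts[t].labels > 0
        out = segment_frame(frames[t], F, np.zeros(F.shape), None, cfg)
        assert not out.unseparated
        assert set(out.present_labels()) == {1, 2}

    def test_occluding_with_true_edges_separates(self, occluding_sequence, cfg):
        frames, gts, upper = occluding_sequence
        t = int(np.nonzero(upper)[0][0])
        up = gts[t].labels == upper[t]
        low = gts[t].labels == (3 - upper[t])
        E = render_aGT(up, low, 1)
        F = gts[t].labels > 0
        bodies = BodyRegions(masks=synthetic_bodies(gts[t]))
        out = segment_frame(frames[t], F, E, bodies, cfg)
        assert not out.unseparated
        assert set(out.present_labels()) == {1, 2}

    def test_no_edges_no_bodies_flagged(self, occluding_sequence, cfg):
        frames, gts, upper = occluding_sequence
        t = int(np.nonzero(upper)[0][0])
        F = gts[t].labels > 0
        out = segment_frame(frames[t], F, np.zeros(F.shape), None, cfg)
        assert out.unseparated

    def test_output_partitions_foreground(self, occluding_sequence, cfg):
        from sepatrack.preprocess import remove_tails
        frames, gts, upper = occluding_sequence
        t = int(np.nonzero(upper)[0][0])
        up = gts[t].labels == upper[t]
        low = gts[t].labels == (3 - upper[t])
        E = render_aGT(up, low, 1)
        F = gts[t].labels > 0
        bodies = BodyRegions(masks=synthetic_bodies(gts[t]))
        out = segment_frame(frames[t], F, E, bodies, cfg)
        f = remove_tails(F, cfg.tail_opening_radius).pixels
        assert np.array_equal(out.labels > 0, f)
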