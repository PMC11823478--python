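"""Centerline selection, trapezoid ROI and sigmoid fitting region."""

import numpy as np
import pytest

from rownav.cluster import ClusterSet, dbscan, window_reduce
from rownav.components import Baseline
from rownav.errors import DegenerateError, NoRowError
from rownav.rowselect import (
    build_centerline_mask,
    confirm_centerline,
    fitting_region,
    in_trapezoid,
    point_side,
    restrict_mask,
    select_candidates,
    sigmoid_threshold,
    trapezoid_roi,
)


def make_clusters(centroids: dict) -> ClusterSet:
    labels = np.array(sorted(centroids), dtype=np.int64)
    return ClusterSet(labels=labels, centroids=centroids)


class TestSelectCandidates:
    def test_single_cluster_selected_at_cod_one(self):
        cs = make_clusters({0: (110.0, 5.0)})
        assert select_candidates(cs, Baseline(100)) == [0]

    def test_near_cluster_beats_far_cluster_at_initial_cod(self):
        # distances {5, 50}: mean 27.5, 0.65 * 27.5 = 17.875 admits only d=5
        cs = make_clusters({0: (105.0, 0.0), 1: (150.0, 0.0)})
        assert select_candidates(cs, Baseline(100)) == [0]

    def test_cluster_on_baseline_selected_immediately(self):
        cs = make_clusters({0: (100.0, 0.0), 1: (400.0, 0.0)})
        assert select_candidates(cs, Baseline(100)) == [0]

    def test_no_clusters_raises(self):
        with pytest.raises(NoRowError):
            select_candidates(ClusterSet(labels=np.empty(0, dtype=np.int64)), Baseline(0))

    def test_terminates_and_nonempty_for_random_sets(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 20))
            cents = {i: (float(rng.uniform(0, 640)), 0.0) for i in range(n)}
            out = select_candidates(make_clusters(cents), Baseline(int(rng.uniform(0, 640))))
            assert out


class TestPointSide:
    def test_right_of_downward_line(self):
        assert point_side((0, 0), (0, 10), (5, 5)) == 1

    def test_left_of_downward_line(self):
        assert point_side((0, 0), (0, 10), (-5, 5)) == -1

    def test_boundary_convention(self):
        assert point_side((0, 0), (0, 10), (0, 5), on_boundary=1) == 1
        assert point_side((0, 0), (0, 10), (0, 5), on_boundary=-1) == -1

    def test_degenerate_line_rejected(self):
        with pytest.raises(DegenerateError):
            point_side((1, 1), (1, 1), (0, 0))


class TestTrapezoid:
    def test_geometry_symmetric_about_baseline(self):
        roi = trapezoid_roi(Baseline(320), 640, 480)
        (lx1, _), (lx2, _) = roi.left
        (rx1, _), (rx2, _) = roi.right
        assert lx1 + rx1 == pytest.approx(640)       # symmetric at the top
        assert rx1 - lx1 == pytest.approx(0.07 * 640)
        assert abs((lx2 - lx1) / 479) == pytest.approx(1 / 12)

    def test_baseline_midpoint_inside(self):
        roi = trapezoid_roi(Baseline(320), 640, 480)
        assert in_trapezoid(np.array([[320.0, 240.0]]), roi) == 1

    def test_frame_edge_outside(self):
        roi = trapezoid_roi(Baseline(320), 640, 480)
        assert in_trapezoid(np.array([[0.0, 240.0]]), roi) == 0

    def test_empty_cluster_count_zero(self):
        roi = trapezoid_roi(Baseline(320), 640, 480)
        assert in_trapezoid(np.empty((0, 2)), roi) == 0

    def test_count_matches_point_side_definition(self, rng):
        roi = trapezoid_roi(Baseline(320), 640, 480)
        pts = rng.uniform((0, 0), (640, 480), (200, 2))
        expected = sum(
            1 for p in pts
            if point_side(roi.left[0], roi.left[1], tuple(p), on_boundary=1) == 1
            and point_side(roi.right[0], roi.right[1], tuple(p), on_boundary=-1) == -1
        )
        assert in_trapezoid(pts, roi) == expected


class TestCenterlineMask:
    def _setup(self, img):
        pts = window_reduce(img, 8, 8)
        clusters = dbscan(pts, eps=50, min_pts=1)
        return pts, clusters

    def test_single_cluster_keeps_whole_binary(self):
        img = np.zeros((32, 32), dtype=np.uint8)
        img[:, 14:18] = 255
        pts, clusters = self._setup(img)
        mask = build_centerline_mask(list(clusters.centroids), clusters, pts, img)
        assert np.array_equal(mask.mask, img)

    def test_unselected_windows_zeroed(self):
        img = np.zeros((32, 64), dtype=np.uint8)
        img[:, 2:5] = 255
        img[:, 58:61] = 255
        pts = window_reduce(img, 8, 8)
        clusters = dbscan(pts, eps=20, min_pts=1)   # two clusters, far apart
        assert clusters.n_clusters == 2
        keep = [cid for cid in clusters.centroids if clusters.centroids[cid][0] < 30]
        mask = build_centerline_mask(keep, clusters, pts, img)
        assert mask.mask[:, 2:5].all()
        assert not mask.mask[:, 58:61].any()

    def test_union_of_two_selected_clusters(self):
        img = np.zeros((32, 64), dtype=np.uint8)
        img[:, 2:5] = 255
        img[:, 58:61] = 255
        pts = window_reduce(img, 8, 8)
        clusters = dbscan(pts, eps=20, min_pts=1)
        mask = build_centerline_mask(list(clusters.centroids), clusters, pts, img)
        assert np.array_equal(mask.mask, img)

    def test_mask_subset_of_binary(self, rng):
        img = np.where(rng.random((40, 40)) < 0.3, 255, 0).astype(np.uint8)
        pts, clusters = self._setup(img)
        mask = build_centerline_mask(list(clusters.centroids), clusters, pts, img)
        assert not (mask.mask > img).any()

    def test_empty_selection_rejected(self):
        img = np.full((8, 8), 255, dtype=np.uint8)
        pts, clusters = self._setup(img)
        with pytest.raises(NoRowError):
            build_centerline_mask([], clusters, pts, img)


class TestSigmoid:
    @pytest.mark.parametrize("nzpr, expected", [
        (0.0184, 0.95),
        (0.0896, 0.91),
        (0.2232, 0.76),
    ])
    def test_worked_values(self, nzpr, expected):
        assert sigmoid_threshold(nzpr) == pytest.approx(expected, abs=0.005)

    def test_midpoint(self):
        assert sigmoid_threshold(0.354) == pytest.approx(0.5)

    def test_strictly_decreasing_and_bounded(self):
        grid = np.linspace(0, 1, 501)
        vals = [sigmoid_threshold(z) for z in grid]
        assert all(b < a for a, b in zip(vals, vals[1:]))
        assert all(0 < v < 1 for v in vals)


class TestFittingRegion:
    def _triangle_mask(self, w=101, h=120, peak=50):
        # triangular column projection peaking at `peak`
        img = np.zeros((h, w), dtype=np.uint8)
        for c in range(w):
            n = max(0, 100 - 2 * abs(c - peak))
            img[:n, c] = 255
        return img

    def test_cut_line_value(self):
        mask = np.zeros((120, 40), dtype=np.uint8)
        mask[:100, 20] = 255
        region = fitting_region(mask, t=0.76, baseline=Baseline(20))
        assert region.line_y == pytest.approx((1.2 - 0.76) * 100)

    def test_constant_projection_spans_full_width(self):
        mask = np.full((50, 30), 255, dtype=np.uint8)
        region = fitting_region(mask, t=0.9, baseline=Baseline(15))
        assert (region.col_lo, region.col_hi) == (0, 29)

    def test_triangular_projection_matches_scan_oracle(self):
        mask = self._triangle_mask()
        t = 0.8
        region = fitting_region(mask, t, baseline=Baseline(50))
        counts = (mask > 0).sum(axis=0)
        cut = (1.2 - t) * counts.max()
        inside = np.flatnonzero(counts >= cut)
        runs = np.split(inside, np.flatnonzero(np.diff(inside) > 1) + 1)
        want = next(r for r in runs if 50 in r)
        assert (region.col_lo, region.col_hi) == (want[0], want[-1])

    def test_region_contains_baseline(self):
        mask = self._triangle_mask()
        region = fitting_region(mask, 0.85, baseline=Baseline(52))
        assert region.col_lo <= 52 <= region.col_hi

    def test_monotone_shrinkage_in_nzpr(self):
        mask = self._triangle_mask()
        widths = []
        for nzpr in (0.02, 0.1, 0.25, 0.4):
            region = fitting_region(mask, sigmoid_threshold(nzpr), Baseline(50))
            widths.append(region.col_hi - region.col_lo)
        assert all(b <= a for a, b in zip(widths, widths[1:]))

    def test_outermost_mode_spans_all_runs(self):
        mask = np.zeros((60, 50), dtype=np.uint8)
        mask[:50, 10] = 255
        mask[:50, 40] = 255
        region = fitting_region(mask, 0.9, Baseline(10), outermost=True)
        assert (region.col_lo, region.col_hi) == (10, 40)

    def test_empty_mask_rejected(self):
        with pytest.raises(NoRowError):
            fitting_region(np.zeros((10, 10), dtype=np.uint8), 0.9, Baseline(5))

    def test_restrict_mask_zeroes_outside(self):
        mask = self._triangle_mask()
        region = fitting_region(mask, 0.8, Baseline(50))
        out = restrict_mask(mask, region)
        assert not out[:, :region.col_lo].any()
        assert not out[:, region.col_hi + 1:].any()
        assert np.array_equal(out[:, region.col_lo:region.col_hi + 1],
                              mask[:, region.col_lo:region.col_hi + 1])


class TestConfirmCenterline:
    def test_gap_scene_selects_both_flanking_clusters(self):
        # a near-vertical row with a long mid-row gap splits into two
        # clusters; both must survive the trapezoid confirmation
        img = np.zeros((480, 640), dtype=np.uint8)
        img[:140, 316:324] = 255
        img[400:, 316:324] = 255
        pts = window_reduce(img, 8, 8)
        clusters = dbscan(pts, eps=200, min_pts=4)
        assert clusters.n_clusters == 2
        baseline = Baseline(320)
        candidates = select_candidates(clusters, baseline)
        roi = trapezoid_roi(baseline, 640, 480)
        confirmed = confirm_centerline(candidates, clusters, pts, roi)
        assert sorted(confirmed) == sorted(clusters.centroids)
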