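"""Centerline selection and sigmoid-segmented fitting region.

The central plantation row is picked in two passes: a coefficient-of-
distance sweep keeps clusters whose centroid lies close to the baseline,
then an isosceles trapezoidal ROI (baseline as its median) confirms each
candidate via signed cross products — clusters with at least one point
inside survive.  Several clusters may jointly form the centerline, which
is what makes seedling-absence gaps recoverable.

The fitting region is then cut out of the centerline mask with an
NZPR-driven sigmoid threshold: denser rows (higher NZPR) get a lower
threshold, i.e. a higher projection cut line and a tighter region around
the stem.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .cluster import ClusterSet, PointSet
from .components import Baseline, vertical_projection
from .errors import DegenerateError, NoRowError

Point = tuple[float, float]


@dataclass(frozen=True)
class TrapezoidROI:
    """Two full-height oblique lines symmetric about the baseline column.

    Width at the image top is ``top_frac * W``; each side drifts outward
    going down with |dx/dy| = ``slope`` (rows look narrower at the top
    under perspective).  Each line is stored top point first.
    """

    left: tuple[Point, Point]
    right: tuple[Point, Point]
    baseline_x: float


@dataclass
class CenterlineMask:
    mask: np.ndarray
    selected_ids: list[int]


@dataclass(frozen=True)
class FittingRegion:
    col_lo: int          # inclusive
    col_hi: int          # inclusive
    threshold_t: float
    line_y: float


def select_candidates(clusters: ClusterSet, baseline: Baseline,
                      cod0: float = 0.65, step: float = 0.05) -> list[int]:
    """Clusters whose centroid-to-baseline distance is within cod * mean.

    The coefficient of distance starts at ``cod0`` and grows by ``step``
    until at least one cluster qualifies; once ``cod * mean`` reaches the
    maximum distance every cluster qualifies, so the sweep terminates.
    """
    if clusters.n_clusters == 0:
        raise NoRowError("no clusters to select a centerline from")
    ids = sorted(clusters.centroids)
    d = np.array([abs(clusters.centroids[i][0] - baseline.column) for i in ids])
    d_mean = d.mean()
    cod = cod0
    while True:
        selected = [ids[k] for k in np.flatnonzero(d <= cod * d_mean)]
        if selected:
            return selected
        if cod * d_mean >= d.max():          # unreachable guard: everything qualifies here
            return ids
        cod += step


def point_side(a: Point, b: Point, c: Point, on_boundary: int = 1) -> int:
    """Signed side of point ``c`` relative to the directed line a -> b.

    Returns -1 when the cross product (b-a) x (c-a) is positive, +1 when
    negative.  An exactly-on-line point takes ``on_boundary`` (+1 for the
    left-line test, -1 for the right-line test: boundary inclusive).
    """
    if a == b:
        raise DegenerateError("a and b coincide; no line defined")
    cross = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
    if cross > 0:
        return -1
    if cross < 0:
        return 1
    return on_boundary


def trapezoid_roi(baseline: Baseline, width: int, height: int,
                  top_frac: float = 0.07, slope: float = 1.0 / 12.0) -> TrapezoidROI:
    half_top = top_frac * width / 2.0
    dy = float(height - 1)
    bx = float(baseline.column)
    left = ((bx - half_top, 0.0), (bx - half_top - slope * dy, dy))
    right = ((bx + half_top, 0.0), (bx + half_top + slope * dy, dy))
    return TrapezoidROI(left=left, right=right, baseline_x=bx)


def in_trapezoid(points: np.ndarray, roi: TrapezoidROI) -> int:
    """Count of points inside the trapezoid (boundary inclusive).

    A point is inside when it lies to the right of the left oblique line
    and to the left of the right one, both directed top to bottom.
    """
    pts = np.asarray(points, dtype=np.float64).reshape(-1, 2)
    if len(pts) == 0:
        return 0
    (lax, lay), (lbx, lby) = roi.left
    (rax, ray), (rbx, rby) = roi.right
    cross_l = (lbx - lax) * (pts[:, 1] - lay) - (lby - lay) * (pts[:, 0] - lax)
    cross_r = (rbx - rax) * (pts[:, 1] - ray) - (rby - ray) * (pts[:, 0] - rax)
    inside = (cross_l <= 0) & (cross_r >= 0)   # boundary inclusive on both sides
    return int(inside.sum())


def confirm_centerline(candidate_ids: list[int], clusters: ClusterSet,
                       points: PointSet, roi: TrapezoidROI) -> list[int]:
    """Candidates with at least one point inside the trapezoid ROI."""
    confirmed = [cid for cid in candidate_ids
                 if in_trapezoid(points.points[clusters.members(cid)], roi) > 0]
    return confirmed


def build_centerline_mask(selected_ids: list[int], clusters: ClusterSet,
                          points: PointSet, binary: np.ndarray) -> CenterlineMask:
    """Full-resolution mask of the pixels behind the selected clusters.

    A pixel is kept when its covering reduce-window produced a point
    assigned to a selected cluster (the union over selected clusters).
    """
    if not selected_ids:
        raise NoRowError("no clusters selected for the centerline")
    binary = np.asarray(binary)
    grid_h, grid_w = points.grid_shape
    w, h = points.window
    keep = np.zeros(grid_h * grid_w, dtype=bool)
    sel = np.isin(clusters.labels, selected_ids)
    keep[points.source_window[sel]] = True
    keep_grid = keep.reshape(grid_h, grid_w)
    pixel_keep = np.repeat(np.repeat(keep_grid, h, axis=0), w, axis=1)
    pixel_keep = pixel_keep[:binary.shape[0], :binary.shape[1]]
    mask = np.where(pixel_keep & (binary > 0), 255, 0).astype(np.uint8)
    return CenterlineMask(mask=mask, selected_ids=list(selected_ids))


def sigmoid_threshold(nzpr: float, k: float = -8.67, x0: float = 0.354) -> float:
    """NZPR-driven segmentation threshold t = 1 / (1 + exp(-k (NZPR - x0))).

    With k = -8.67 the map is strictly decreasing in NZPR and bounded in
    (0, 1): sparse early-stage rows get a high threshold (keep almost the
    whole projection), dense rows a low one (cut down to the stem).
    ``nzpr`` is a fraction in [0, 1].
    """
    return 1.0 / (1.0 + math.exp(-k * (nzpr - x0)))


def fitting_region(mask: np.ndarray, t: float, baseline: Baseline,
                   cut_coeff: float = 1.2, outermost: bool = False) -> FittingRegion:
    """Column interval of the centerline mask above the sigmoid cut line.

    The cut line sits at ``(cut_coeff - t) * y_max`` on the column
    projection of the mask.  By default the region is the maximal
    contiguous super-threshold run containing the baseline column (if the
    baseline column itself falls below the cut, the run containing the
    projection maximum is used); with ``outermost=True`` it spans from
    the first to the last super-threshold column.
    """
    mask = np.asarray(mask)
    prof = vertical_projection(mask)
    counts = prof.counts
    if counts.max() == 0:
        raise NoRowError("empty centerline mask")
    line_y = (cut_coeff - t) * counts.max()
    above = counts >= line_y
    cols = np.flatnonzero(above)
    if cols.size == 0:      # only possible for t <= cut_coeff - 1
        raise NoRowError("no column reaches the projection cut line")
    if outermost:
        lo, hi = int(cols[0]), int(cols[-1])
    else:
        anchor = baseline.column if above[min(baseline.column, len(counts) - 1)] \
            else int(np.argmax(counts))
        lo = anchor
        while lo > 0 and above[lo - 1]:
            lo -= 1
        hi = anchor
        while hi < len(counts) - 1 and above[hi + 1]:
            hi += 1
    return FittingRegion(col_lo=lo, col_hi=hi, threshold_t=t, line_y=float(line_y))


def restrict_mask(mask: np.ndarray, region: FittingRegion) -> np.ndarray:
    """Zero out all columns outside the fitting region."""
    out = np.zeros_like(mask)
    out[:, region.col_lo:region.col_hi + 1] = mask[:, region.col_lo:region.col_hi + 1]
    return out
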