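"""Pixel reduction and density clustering of the crop mask.

Foreground pixels are reduced with a non-overlapping sliding-window mean
(one representative point per occupied window), then grouped into
plantation-row clusters with DBSCAN whose radius queries are served by a
KD-tree — sub-quadratic in the number of points.  Point order follows the
raster order of the windows, which makes border-point assignment
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import ConfigError

NOISE = -1


@dataclass
class PointSet:
    """Reduced 2-D points in image pixel coordinates (fractional allowed).

    ``source_window`` gives each point's flat window index in the
    ``(grid_h, grid_w)`` raster of reduce windows, so full-resolution
    pixels can be traced back to their representative point.
    """

    points: np.ndarray                      # (n, 2) float64, columns (x, y)
    source_window: np.ndarray               # (n,) int64
    grid_shape: tuple[int, int]             # (grid_h, grid_w)
    window: tuple[int, int]                 # (w, h)

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class ClusterSet:
    """DBSCAN labeling of a PointSet: -1 is noise, 0..k-1 are clusters."""

    labels: np.ndarray                      # (n,) int64
    centroids: dict[int, tuple[float, float]] = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(self.centroids)

    def members(self, cid: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cid)


def window_reduce(img: np.ndarray, w: int = 8, h: int = 8) -> PointSet:
    """One mean point per non-empty ``w x h`` window (step = window size).

    Windows tile the image without overlap; partial windows at the right
    and bottom edges are included.  Each window holding at least one
    foreground pixel yields the mean (x, y) of its foreground pixels.
    """
    if w < 1 or h < 1:
        raise ConfigError(f"window must be >= 1x1, got {w}x{h}")
    img = np.asarray(img)
    ys, xs = np.nonzero(img > 0)
    grid_w = -(-img.shape[1] // w)
    grid_h = -(-img.shape[0] // h)
    n_windows = grid_w * grid_h
    if len(ys) == 0:
        return PointSet(points=np.empty((0, 2)), source_window=np.empty(0, dtype=np.int64),
                        grid_shape=(grid_h, grid_w), window=(w, h))
    win = (ys // h) * grid_w + (xs // w)
    counts = np.bincount(win, minlength=n_windows)
    sum_x = np.bincount(win, weights=xs, minlength=n_windows)
    sum_y = np.bincount(win, weights=ys, minlength=n_windows)
    occupied = np.flatnonzero(counts)       # ascending = raster order
    pts = np.column_stack((sum_x[occupied] / counts[occupied],
                           sum_y[occupied] / counts[occupied]))
    return PointSet(points=pts, source_window=occupied.astype(np.int64),
                    grid_shape=(grid_h, grid_w), window=(w, h))


def _dbscan_labels(points: np.ndarray, neighbors: list[np.ndarray],
                   min_pts: int) -> np.ndarray:
    """Queue-based DBSCAN expansion given precomputed eps-neighborhoods.

    Seeds are processed in point (raster) order; a border point reachable
    from several clusters is claimed by the first cluster to reach it.
    """
    n = len(points)
    labels = np.full(n, NOISE, dtype=np.int64)
    visited = np.zeros(n, dtype=bool)
    cluster_id = 0
    for i in range(n):
        if visited[i]:
            continue
        visited[i] = True
        if len(neighbors[i]) < min_pts:
            continue                         # noise unless claimed later
        labels[i] = cluster_id
        queue = list(neighbors[i])
        qpos = 0
        while qpos < len(queue):
            j = queue[qpos]
            qpos += 1
            if labels[j] == NOISE:
                labels[j] = cluster_id
            if not visited[j]:
                visited[j] = True
                if len(neighbors[j]) >= min_pts:
                    queue.extend(neighbors[j])
        cluster_id += 1
    return labels


def dbscan(points: PointSet | np.ndarray, eps: float = 200.0,
           min_pts: int = 4) -> ClusterSet:
    """DBSCAN with KD-tree neighbor queries.

    Core points have >= ``min_pts`` neighbors (self included) within
    Euclidean ``eps``; clusters are the core-reachable sets and
    unreachable points are labeled noise (-1).  The partition is
    identical to a naive O(n^2) DBSCAN under the same point ordering.
    """
    if eps <= 0 or min_pts < 1:
        raise ConfigError("eps must be > 0 and min_pts >= 1")
    pts = points.points if isinstance(points, PointSet) else np.asarray(points, dtype=np.float64)
    if len(pts) == 0:
        return ClusterSet(labels=np.empty(0, dtype=np.int64))
    tree = cKDTree(pts)
    neighbors = [np.sort(np.asarray(nb, dtype=np.int64))
                 for nb in tree.query_ball_point(pts, r=eps)]
    labels = _dbscan_labels(pts, neighbors, min_pts)
    centroids = {int(cid): (float(pts[labels == cid, 0].mean()),
                            float(pts[labels == cid, 1].mean()))
                 for cid in np.unique(labels) if cid != NOISE}
    return ClusterSet(labels=labels, centroids=centroids)
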