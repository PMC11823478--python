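"""Robust navigation-line fitting: RANSAC consensus + least-squares refit.

Feature points are extracted from the fitting mask with a 16x32 sliding
window (wide-short windows follow the near-vertical row shape), a seeded
RANSAC maximizes the inlier count under a perpendicular-distance
threshold, and the final line is the least-squares fit over the inlier
set only — this keeps the line from drifting toward the density center
of the points.

Rows are near-vertical, so regression is performed axis-swapped
(x as a function of y); see :mod:`rownav.geometry`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .cluster import PointSet, window_reduce
from .errors import DegenerateError, NoRowError
from .geometry import Line


@dataclass(frozen=True)
class RansacConfig:
    """RANSAC constants.

    ``dist_thresh`` is interpreted in width-normalized coordinates when
    ``normalized`` is True (coordinates divided by the image width before
    fitting), otherwise in raw pixels.
    """

    dist_thresh: float = 0.155
    confidence: float = 0.99
    min_model_points: int = 2
    max_iter: int = 10_000
    normalized: bool = True


def feature_points(mask: np.ndarray, w: int = 16, h: int = 32) -> PointSet:
    """Window-mean feature points of the fitting mask (w x h windows)."""
    pts = window_reduce(mask, w=w, h=h)
    if len(pts) == 0:
        raise NoRowError("fitting mask contains no foreground")
    return pts


def ransac_iterations(cl: float, p: float, n: int = 2,
                      max_iter: int = 10_000) -> int:
    """Iterations k = ceil(log(1-CL) / log(1-p^n)) for confidence CL.

    ``p`` is the current inlier ratio; p = 1 needs a single draw, p -> 0
    saturates at ``max_iter``.
    """
    if p >= 1.0:
        return 1
    if p <= 0.0:
        return max_iter
    denom = math.log(1.0 - p ** n)
    if denom == 0.0:
        return max_iter
    k = math.ceil(math.log(1.0 - cl) / denom)
    return int(min(max(k, 1), max_iter))


def _point_line_distance(pts: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    """Perpendicular distances from pts to the line through p1, p2."""
    d = p2 - p1
    norm = np.hypot(d[0], d[1])
    return np.abs(d[0] * (pts[:, 1] - p1[1]) - d[1] * (pts[:, 0] - p1[0])) / norm


def ransac_line(points: PointSet | np.ndarray, cfg: RansacConfig = RansacConfig(),
                seed: int = 0, width: float | None = None,
                height: int | None = None) -> tuple[Line, np.ndarray]:
    """Consensus line through 2-point samples; returns (line, inlier indices).

    Maximizes the number of points within ``dist_thresh`` perpendicular
    distance; ties are broken by lower total inlier residual.  The
    iteration count adapts downward as the best inlier ratio improves
    (initially two inliers are assumed).  Sampling is driven by a seeded
    generator, so results are reproducible.
    """
    pts = points.points if isinstance(points, PointSet) else np.asarray(points, dtype=np.float64)
    if len(pts) < 2:
        raise NoRowError(f"need >= 2 points to fit a line, got {len(pts)}")
    if np.allclose(pts, pts[0]):
        raise DegenerateError("all points coincide")
    scale = 1.0
    if cfg.normalized:
        scale = float(width) if width is not None else float(pts[:, 0].max() - pts[:, 0].min() or 1.0)
    work = pts / scale
    n = len(work)
    rng = np.random.default_rng(seed)
    best_inliers: np.ndarray | None = None
    best_score = (-1, np.inf)
    p_best = 2.0 / n                     # initial inlier count of 2
    k = ransac_iterations(cfg.confidence, p_best, cfg.min_model_points, cfg.max_iter)
    i = 0
    while i < k:
        i += 1
        idx = rng.choice(n, size=2, replace=False)
        p1, p2 = work[idx[0]], work[idx[1]]
        if np.array_equal(p1, p2):
            continue
        dist = _point_line_distance(work, p1, p2)
        inl = dist < cfg.dist_thresh
        count = int(inl.sum())
        resid = float(dist[inl].sum())
        if (count, -resid) > (best_score[0], -best_score[1]):
            best_score = (count, resid)
            best_inliers = np.flatnonzero(inl)
            p_best = max(p_best, count / n)
            k = min(k, ransac_iterations(cfg.confidence, p_best,
                                         cfg.min_model_points, cfg.max_iter))
    if best_inliers is None or len(best_inliers) < 2:
        raise DegenerateError("RANSAC found no 2-point consensus")
    line = lsq_refit(pts, best_inliers, height=height)
    return line, best_inliers


def lsq_refit(points: PointSet | np.ndarray, inliers: np.ndarray,
              height: int | None = None) -> Line:
    """Least-squares line over the inlier set only, axis-swapped (x = a*y + b).

    If the inliers share a single y value (a horizontal run, impossible
    for a real crop row but reachable on adversarial input) the fit falls
    back to total least squares.
    """
    pts = points.points if isinstance(points, PointSet) else np.asarray(points, dtype=np.float64)
    sel = pts[np.asarray(inliers, dtype=np.int64)]
    if len(sel) < 2:
        raise DegenerateError(f"need >= 2 inliers, got {len(sel)}")
    if np.allclose(sel, sel[0]):
        raise DegenerateError("all inliers coincide")
    x, y = sel[:, 0], sel[:, 1]
    if height is None:
        height = int(math.ceil(y.max())) + 1
    if np.ptp(y) == 0.0:
        # total least squares via the principal direction
        centered = sel - sel.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        dx, dy = vt[0]
        if dy == 0.0:
            raise DegenerateError("inliers are exactly horizontal; no x = a*y + b form")
        a = dx / dy
        b = sel[:, 0].mean() - a * sel[:, 1].mean()
        return Line(a=float(a), b=float(b), height=height)
    design = np.column_stack((y, np.ones_like(y)))
    (a, b), *_ = np.linalg.lstsq(design, x, rcond=None)
    return Line(a=float(a), b=float(b), height=height)


def fit_navigation_line(points: PointSet, height: int, width: float,
                        cfg: RansacConfig = RansacConfig(),
                        seed: int = 0) -> tuple[Line, np.ndarray]:
    """RANSAC + least-squares refit, with endpoints pinned to the frame."""
    return ransac_line(points, cfg=cfg, seed=seed, width=width, height=height)
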