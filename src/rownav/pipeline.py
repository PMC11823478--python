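"""End-to-end orchestration: RGB frame in, navigation line out.

Stages run in the fixed order preprocess -> components -> cluster ->
rowselect -> fitline.  Every stage failure is converted into a typed
status on the result — frames without vegetation or without an
identifiable row are legitimate field conditions, not crashes.  Identical
input, config and seed give identical results.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from . import cluster as _cluster
from . import components as _components
from . import fitline as _fitline
from . import preprocess as _preprocess
from . import rowselect as _rowselect
from .config import PipelineConfig
from .errors import DegenerateError, NoRowError, NoVegetationError
from .geometry import Line

STATUS_OK = "ok"
STATUS_NO_VEGETATION = "no_vegetation"
STATUS_NO_ROW = "no_row"
STATUS_DEGENERATE = "degenerate"


@dataclass
class PipelineResult:
    """Navigation line plus per-stage diagnostics for one frame."""

    status: str
    line: Line | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return self.status == STATUS_OK

    def to_dict(self) -> dict:
        return {
            "status": self.status,
            "line": self.line.to_dict() if self.line is not None else None,
            "diagnostics": self.diagnostics,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def run_pipeline(img: np.ndarray, cfg: PipelineConfig | None = None) -> PipelineResult:
    """Extract the navigation line of the central crop row from one frame.

    The image is resized to ``cfg.resolution`` if needed.  On success the
    result carries the fitted :class:`~rownav.geometry.Line`; otherwise a
    typed failure status with the diagnostics accumulated so far.
    """
    cfg = cfg or PipelineConfig()
    diag: dict = {}
    w, h = cfg.resolution
    img = _preprocess.resize_image(np.asarray(img), cfg.resolution, letterbox=cfg.letterbox)
    try:
        binary, pre_diag = _preprocess.preprocess(img, cfg)
        diag.update(pre_diag)

        lbl = _components.label_components(binary)
        diag["n_components"] = lbl.n_components
        filtered = _components.filter_components(lbl, c=cfg.c_area)
        prof = _components.vertical_projection(filtered, roi_frac=cfg.roi_frac)
        baseline = _components.detect_baseline(prof)
        diag["baseline_column"] = baseline.column

        points = _cluster.window_reduce(filtered, *cfg.reduce_window)
        diag["n_points"] = len(points)
        clusters = _cluster.dbscan(points, eps=cfg.effective_eps, min_pts=cfg.min_pts)
        diag["n_clusters"] = clusters.n_clusters

        candidates = _rowselect.select_candidates(clusters, baseline,
                                                  cod0=cfg.cod0, step=cfg.cod_step)
        roi = _rowselect.trapezoid_roi(baseline, w, h, top_frac=cfg.trapezoid_top_frac,
                                       slope=cfg.trapezoid_slope)
        confirmed = _rowselect.confirm_centerline(candidates, clusters, points, roi)
        if not confirmed:
            # distance sweep found candidates, but none reaches the trapezoid
            raise NoRowError("no candidate cluster intersects the trapezoid ROI")
        diag["selected_clusters"] = confirmed
        center = _rowselect.build_centerline_mask(confirmed, clusters, points, filtered)

        nzpr_center = _preprocess.compute_nzpr(center.mask)
        t = _rowselect.sigmoid_threshold(nzpr_center, k=cfg.sigmoid_k, x0=cfg.sigmoid_x0)
        diag["centerline_nzpr"] = nzpr_center
        diag["sigmoid_t"] = t
        region = _rowselect.fitting_region(center.mask, t, baseline,
                                           cut_coeff=cfg.cut_coeff,
                                           outermost=cfg.fitting_outermost)
        diag["fitting_interval"] = [region.col_lo, region.col_hi]
        fit_mask = _rowselect.restrict_mask(center.mask, region)

        feats = _fitline.feature_points(fit_mask, *cfg.feature_window)
        diag["n_feature_points"] = len(feats)
        rcfg = _fitline.RansacConfig(dist_thresh=cfg.ransac_thresh,
                                     confidence=cfg.ransac_cl,
                                     min_model_points=cfg.ransac_min_points,
                                     max_iter=cfg.ransac_max_iter,
                                     normalized=cfg.ransac_normalized)
        line, inliers = _fitline.fit_navigation_line(feats, height=h, width=w,
                                                     cfg=rcfg, seed=cfg.seed)
        diag["n_inliers"] = len(inliers)
        return PipelineResult(status=STATUS_OK, line=line, diagnostics=diag)
    except NoVegetationError as exc:
        diag["error"] = str(exc)
        return PipelineResult(status=STATUS_NO_VEGETATION, diagnostics=diag)
    except NoRowError as exc:
        diag["error"] = str(exc)
        return PipelineResult(status=STATUS_NO_ROW, diagnostics=diag)
    except DegenerateError as exc:
        diag["error"] = str(exc)
        return PipelineResult(status=STATUS_DEGENERATE, diagnostics=diag)


def render_overlay(img: np.ndarray, result: PipelineResult,
                   cfg: PipelineConfig | None = None) -> np.ndarray:
    """Draw the fitted line and stage artifacts onto a copy of the frame."""
    from skimage.draw import line as draw_line

    cfg = cfg or PipelineConfig()
    out = _preprocess.resize_image(np.asarray(img), cfg.resolution,
                                   letterbox=cfg.letterbox).copy()
    h, w = out.shape[:2]

    def _seg(p1, p2, color):
        x1, y1 = (int(round(min(max(v, 0), lim - 1))) for v, lim in zip(p1, (w, h)))
        x2, y2 = (int(round(min(max(v, 0), lim - 1))) for v, lim in zip(p2, (w, h)))
        rr, cc = draw_line(y1, x1, y2, x2)
        out[rr, cc] = color

    baseline = result.diagnostics.get("baseline_column")
    if baseline is not None:
        _seg((baseline, 0), (baseline, h - 1), (255, 255, 0))
        roi = _rowselect.trapezoid_roi(_components.Baseline(baseline), w, h,
                                       top_frac=cfg.trapezoid_top_frac,
                                       slope=cfg.trapezoid_slope)
        _seg(roi.left[0], roi.left[1], (0, 200, 255))
        _seg(roi.right[0], roi.right[1], (0, 200, 255))
    interval = result.diagnostics.get("fitting_interval")
    if interval is not None:
        for col in interval:
            _seg((col, 0), (col, h - 1), (255, 0, 255))
    if result.line is not None:
        (xt, yt), (xb, yb) = result.line.endpoints
        _seg((xt, yt), (xb, yb), (255, 0, 0))
    else:
        out[:12, :] = (128, 0, 0)       # status banner strip
    return out


def process_image(path: str | Path, cfg: PipelineConfig | None = None) -> PipelineResult:
    """Load a PNG/JPEG frame from disk and run the pipeline on it."""
    with Image.open(path) as pil:
        img = np.asarray(pil.convert("RGB"))
    return run_pipeline(img, cfg)
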