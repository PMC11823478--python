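"""Connected-component filtering and column-projection baseline detection.

Morphological opening leaves small disconnected specks; components whose
area falls below a fraction of the mean component area are removed.  The
vertical (column) projection of the cleaned mask then locates the
baseline: the column with the maximum foreground count inside the central
35% of the image, which predicts the central crop row's position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import NoVegetationError

_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass
class LabelImage:
    """8-connected component labeling of a binary image.

    ``labels`` holds 0 for background and 1..n_components otherwise;
    ``areas[k]`` is the pixel count of component ``k`` (``areas[0]`` is
    the background count and is never used for filtering).
    """

    labels: np.ndarray
    areas: np.ndarray
    n_components: int


@dataclass
class ProjectionProfile:
    """Per-column foreground counts plus the half-open baseline ROI [roi_lo, roi_hi)."""

    counts: np.ndarray
    roi_lo: int
    roi_hi: int


@dataclass(frozen=True)
class Baseline:
    column: int


def label_components(img: np.ndarray) -> LabelImage:
    """Label 8-connected foreground components (diagonal contact connects)."""
    fg = np.asarray(img) > 0
    labels, n = ndimage.label(fg, structure=_STRUCT8)
    areas = np.bincount(labels.ravel(), minlength=n + 1)
    return LabelImage(labels=labels, areas=areas, n_components=int(n))


def filter_components(lbl: LabelImage, c: float = 0.7) -> np.ndarray:
    """Keep components with area >= c * (mean component area).

    With zero components the output is empty.  The mean is taken over all
    components, specks included.
    """
    if lbl.n_components == 0:
        return np.zeros_like(lbl.labels, dtype=np.uint8)
    comp_areas = lbl.areas[1:].astype(np.float64)
    thresh = comp_areas.mean() * c
    keep = np.concatenate(([False], comp_areas >= thresh))
    return np.where(keep[lbl.labels], 255, 0).astype(np.uint8)


def vertical_projection(img: np.ndarray, roi_frac: float = 0.35) -> ProjectionProfile:
    """Column-wise foreground counts with the central-``roi_frac`` ROI."""
    img = np.asarray(img)
    counts = (img > 0).sum(axis=0)
    w = img.shape[1]
    lo = int(round((0.5 - roi_frac / 2.0) * w))
    hi = int(round((0.5 + roi_frac / 2.0) * w))
    return ProjectionProfile(counts=counts, roi_lo=lo, roi_hi=hi)


def detect_baseline(prof: ProjectionProfile) -> Baseline:
    """Column of the maximum projection count inside the ROI.

    Ties are broken toward the column nearest the image center, then
    toward the smaller column.  An all-zero ROI means no vegetation where
    a crop row is required, which aborts the frame.
    """
    roi = prof.counts[prof.roi_lo:prof.roi_hi]
    if roi.size == 0 or roi.max() == 0:
        raise NoVegetationError("no foreground in the baseline ROI")
    best = roi.max()
    candidates = np.flatnonzero(roi == best) + prof.roi_lo
    center = len(prof.counts) / 2.0
    # lexicographic: distance to center, then column index
    order = np.lexsort((candidates, np.abs(candidates - center)))
    return Baseline(column=int(candidates[order[0]]))
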