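"""Pipeline configuration: every tunable constant of the algorithm.

Defaults are the values the method was developed with; all are
overridable programmatically or through a flat YAML file that mirrors the
dataclass field names exactly.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .errors import ConfigError

SUPPORTED_RESOLUTIONS: tuple[tuple[int, int], ...] = ((640, 480), (1920, 1080))


@dataclass
class PipelineConfig:
    """All algorithm constants, with the method's published defaults.

    Attributes
    ----------
    resolution : (width, height)
        Working resolution; inputs are resized to it. One of 640x480 or
        1920x1080.
    k_otsu :
        Proportion coefficient applied to the Otsu threshold (binarize at
        ``gray > k_otsu * t_star``).
    c_area :
        Connected-component area coefficient: components smaller than
        ``c_area`` times the mean component area are removed.
    roi_frac :
        Central column fraction searched for the baseline.
    reduce_window : (w, h)
        Sliding-window size for pixel reduction before clustering.
    eps, min_pts :
        DBSCAN neighborhood radius (pixels) and minimum neighbor count.
    eps_scale_with_width :
        If True, eps is rescaled as ``eps * width / 1920`` so the printed
        radius tracks the working resolution.
    cod0, cod_step :
        Initial coefficient-of-distance for centroid selection and its
        per-iteration increment.
    trapezoid_top_frac, trapezoid_slope :
        Trapezoidal ROI: top width as a fraction of image width, and the
        |dx/dy| of its oblique sides.
    sigmoid_k, sigmoid_x0 :
        Parameters of the NZPR-driven sigmoid threshold.
    cut_coeff :
        Coefficient of the projection cut level ``(cut_coeff - t) * y_max``.
    fitting_outermost :
        If True the fitting interval spans the outermost super-threshold
        columns instead of the baseline-containing contiguous run.
    feature_window : (w, h)
        Sliding-window size for feature-point extraction before fitting.
    ransac_thresh, ransac_cl, ransac_min_points, ransac_max_iter :
        RANSAC distance threshold, confidence level, minimal model size
        and iteration cap.
    ransac_normalized :
        If True (default) point coordinates are normalized by image width
        before RANSAC so the distance threshold is in width units.
    seed :
        RNG seed for RANSAC sampling; fixed so runs are reproducible.
    letterbox :
        Pad to preserve aspect ratio when resizing instead of stretching.
    """

    resolution: tuple[int, int] = (640, 480)
    k_otsu: float = 0.8
    c_area: float = 0.7
    roi_frac: float = 0.35
    reduce_window: tuple[int, int] = (8, 8)
    eps: float = 200.0
    min_pts: int = 4
    eps_scale_with_width: bool = False
    cod0: float = 0.65
    cod_step: float = 0.05
    trapezoid_top_frac: float = 0.07
    trapezoid_slope: float = 1.0 / 12.0
    sigmoid_k: float = -8.67
    sigmoid_x0: float = 0.354
    cut_coeff: float = 1.2
    fitting_outermost: bool = False
    feature_window: tuple[int, int] = (16, 32)
    ransac_thresh: float = 0.155
    ransac_cl: float = 0.99
    ransac_min_points: int = 2
    ransac_max_iter: int = 10_000
    ransac_normalized: bool = True
    morphology_enabled: bool = True
    seed: int = 0
    letterbox: bool = False

    def __post_init__(self) -> None:
        self.resolution = tuple(self.resolution)  # type: ignore[assignment]
        self.reduce_window = tuple(self.reduce_window)  # type: ignore[assignment]
        self.feature_window = tuple(self.feature_window)  # type: ignore[assignment]
        if self.resolution not in SUPPORTED_RESOLUTIONS:
            raise ConfigError(
                f"unsupported resolution {self.resolution}; "
                f"expected one of {SUPPORTED_RESOLUTIONS}")
        if not (0.0 < self.k_otsu <= 1.0):
            raise ConfigError(f"k_otsu must be in (0, 1], got {self.k_otsu}")
        if self.eps <= 0 or self.min_pts < 1:
            raise ConfigError("eps must be > 0 and min_pts >= 1")
        if not (0.0 < self.ransac_cl < 1.0):
            raise ConfigError("ransac_cl must be in (0, 1)")
        if self.ransac_thresh <= 0:
            raise ConfigError("ransac_thresh must be > 0")

    @property
    def effective_eps(self) -> float:
        if self.eps_scale_with_width:
            return self.eps * self.resolution[0] / 1920.0
        return self.eps

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("resolution", "reduce_window", "feature_window"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
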