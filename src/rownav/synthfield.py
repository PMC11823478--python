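"""Seeded synthetic field scenes with known ground-truth center rows.

The generator emulates the geometry the pipeline targets: near-vertical
crop seedling rows converging toward a vanishing point above the frame
(a camera looking down-field at a declination angle), plants rendered as
rosettes of green elliptical leaf strokes over textured soil, optional
off-row weeds, seedling-absence gaps, and low-light / rain conditions.

Everything is drawn from a single seeded generator, so a fixed spec and
seed reproduce the image bit for bit.  Leaf colors live in a green band
that the excess-green index separates from every soil-palette color by
construction, which keeps the preprocessing tests sharp; the generator
makes no attempt at photorealism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import line as draw_line

from .errors import ConfigError
from .evaluate import Annotation
from .geometry import Line

CONDITIONS = ("normal", "low_light", "rain")

# browns with 2G - R - B <= -24: soil stays strictly non-green even where a
# dark albedo blotch shrinks the deficit and the grain pulls against it, so
# ExG maps soil to exactly zero
SOIL_PALETTE = ((110, 73, 60), (130, 83, 70), (95, 63, 55), (140, 88, 75))


@dataclass(frozen=True)
class SceneSpec:
    """Description of one synthetic field scene.

    Geometry is stated at the image bottom (the near field); plant and
    leaf sizes shrink toward the vanishing point with the perspective
    scale.  ``center_angle_deg`` is the ground-truth center-row angle
    vs. the image-bottom horizontal (90 = vertical).
    """

    resolution: tuple[int, int] = (640, 480)
    n_rows: int = 3
    row_spacing_px: float = 260.0
    center_angle_deg: float = 90.0
    center_bottom_x: float | None = None
    vp_height_px: float = 2500.0        # vanishing point this far above y=0
    plant_spacing_px: float = 35.0
    plant_jitter_px: float = 4.0
    leaf_count: tuple[int, int] = (4, 7)
    leaf_len_px: tuple[float, float] = (12.0, 26.0)
    leaf_width_px: tuple[float, float] = (3.0, 6.0)
    weed_count: int = 3
    weed_radius_px: tuple[float, float] = (3.0, 7.0)
    weed_min_off_row_px: float = 60.0
    gap_spec: tuple[tuple[float, float], ...] = ()
    condition: str = "normal"
    seed: int = 0

    def with_gap(self, y_lo: float = 110.0, y_hi: float = 370.0) -> "SceneSpec":
        """A copy with a seedling-absence gap on the center row."""
        return replace(self, gap_spec=((y_lo, y_hi),))


def _center_line(spec: SceneSpec) -> Line:
    w, h = spec.resolution
    cx = spec.center_bottom_x if spec.center_bottom_x is not None else w / 2.0
    theta = math.radians(spec.center_angle_deg)
    a = -1.0 / math.tan(theta) if spec.center_angle_deg != 90.0 else 0.0
    b = cx - a * (h - 1)
    return Line(a=a, b=b, height=h)


def _row_x_of_y(spec: SceneSpec, row_offset: float):
    """x(y) for the row displaced ``row_offset`` px at the image bottom.

    All rows pass through the shared vanishing point on the extended
    center line, so lateral spacing shrinks linearly toward it.
    """
    w, h = spec.resolution
    center = _center_line(spec)
    vp_y = -spec.vp_height_px
    vp_x = center.x_at(vp_y)
    bottom_x = center.x_at(h - 1) + row_offset
    span = (h - 1) - vp_y

    def x_of_y(y: float) -> float:
        t = (y - vp_y) / span
        return vp_x + t * (bottom_x - vp_x)

    return x_of_y


def _perspective_scale(spec: SceneSpec, y: float) -> float:
    vp_y = -spec.vp_height_px
    return (y - vp_y) / ((spec.resolution[1] - 1) - vp_y)


def _paint_soil(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    w, h = spec.resolution
    base = np.array(SOIL_PALETTE[rng.integers(len(SOIL_PALETTE))], dtype=np.float64)
    img = np.tile(base, (h, w, 1))
    # multiplicative albedo blotches preserve soil chromaticity exactly;
    # grain is luminance-correlated (a common additive shift leaves the
    # excess-green index unchanged) with only faint per-channel noise
    blotch = ndimage.gaussian_filter(rng.normal(0.0, 1.0, (h, w)), sigma=18.0)
    blotch *= 0.18 / max(blotch.std(), 1e-9)
    img *= np.clip(1.0 + blotch, 0.5, 1.6)[..., None]
    img += rng.normal(0.0, 6.0, (h, w))[..., None]
    img += rng.normal(0.0, 0.6, (h, w, 3))
    return np.clip(img, 0.0, 255.0)


def _leaf_color(rng: np.random.Generator) -> np.ndarray:
    return np.array([rng.uniform(25, 75), rng.uniform(125, 205), rng.uniform(20, 65)])


def _paint_plant(img: np.ndarray, rng: np.random.Generator, x: float, y: float,
                 scale: float, spec: SceneSpec) -> None:
    h, w = img.shape[:2]
    n_leaves = int(rng.integers(spec.leaf_count[0], spec.leaf_count[1] + 1))
    for _ in range(n_leaves):
        phi = rng.uniform(0.0, math.pi)
        length = rng.uniform(*spec.leaf_len_px) * scale
        width = max(1.0, rng.uniform(*spec.leaf_width_px) * scale)
        # leaf center offset outward along its own axis
        off = rng.uniform(0.3, 0.7) * length
        cy = y + off * math.sin(phi) * rng.choice((-1.0, 1.0))
        cx = x + off * math.cos(phi) * rng.choice((-1.0, 1.0))
        rr, cc = draw_ellipse(cy, cx, max(1.0, length / 2.0), width / 2.0,
                              shape=(h, w), rotation=phi)
        img[rr, cc] = _leaf_color(rng)
    # stem / crown at the row axis
    rr, cc = draw_ellipse(y, x, max(1.5, 3.5 * scale), max(1.5, 3.5 * scale), shape=(h, w))
    img[rr, cc] = _leaf_color(rng)


def _in_gap(spec: SceneSpec, y: float) -> bool:
    return any(lo <= y <= hi for lo, hi in spec.gap_spec)


def generate_scene(spec: SceneSpec) -> tuple[np.ndarray, Annotation]:
    """Render a scene and its ground-truth center-row annotation.

    Returns an ``(H, W, 3)`` uint8 RGB image and an :class:`Annotation`
    holding the exact endpoints of the center-row line at ``y = 0`` and
    ``y = H - 1``.  Deterministic per spec + seed.
    """
    if spec.n_rows < 1:
        raise ConfigError("a scene needs at least one crop row")
    if spec.condition not in CONDITIONS:
        raise ConfigError(f"unknown condition {spec.condition!r}; expected one of {CONDITIONS}")
    w, h = spec.resolution
    rng = np.random.default_rng(spec.seed)
    img = _paint_soil(spec, rng)

    offsets = (np.arange(spec.n_rows) - (spec.n_rows - 1) / 2.0) * spec.row_spacing_px
    row_fns = [_row_x_of_y(spec, off) for off in offsets]
    center_idx = int(np.argmin(np.abs(offsets)))

    for i, x_of_y in enumerate(row_fns):
        y = float(h - 1) - rng.uniform(0, spec.plant_spacing_px / 2)
        while y > 0:
            scale = _perspective_scale(spec, y)
            if not (i == center_idx and _in_gap(spec, y)):
                px = x_of_y(y) + rng.normal(0.0, spec.plant_jitter_px)
                py = y + rng.normal(0.0, spec.plant_jitter_px)
                if -20 < px < w + 20:
                    _paint_plant(img, rng, px, py, scale, spec)
            y -= spec.plant_spacing_px * scale

    # off-row weeds: small green blobs between the rows
    placed = 0
    attempts = 0
    while placed < spec.weed_count and attempts < 50 * max(spec.weed_count, 1):
        attempts += 1
        wx = rng.uniform(0, w - 1)
        wy = rng.uniform(0, h - 1)
        if min(abs(wx - fn(wy)) for fn in row_fns) < spec.weed_min_off_row_px:
            continue
        radius = rng.uniform(*spec.weed_radius_px) * _perspective_scale(spec, wy)
        rr, cc = draw_ellipse(wy, wx, max(1.0, radius), max(1.0, radius * rng.uniform(0.6, 1.4)),
                              shape=(h, w), rotation=rng.uniform(0, math.pi))
        img[rr, cc] = _leaf_color(rng)
        placed += 1

    img = np.clip(img, 0, 255).astype(np.uint8)
    if spec.condition != "normal":
        img = apply_condition(img, spec.condition, seed=spec.seed)

    center = _center_line(spec)
    (xt, yt), (xb, yb) = center.endpoints
    ann = Annotation(image_id=f"scene_{spec.seed}", x1=xt, y1=yt, x2=xb, y2=yb)
    return img, ann


def apply_condition(img: np.ndarray, condition: str, seed: int = 0,
                    gain: float = 0.5, gamma: float = 1.0,
                    n_streaks: int = 160, streak_angle_deg: float = 15.0) -> np.ndarray:
    """Degrade an image with a capture condition.

    ``low_light`` applies a global gain (default 0.5, which halves the
    mean luminance) and an optional gamma, identically on all channels so
    chroma is preserved.  ``rain`` overlays seeded semi-transparent gray
    streaks inclined ``streak_angle_deg`` from vertical, then mildly
    blurs and darkens the frame.  ``normal`` is the identity.
    """
    img = np.asarray(img)
    if condition == "normal":
        return img.copy()
    if condition == "low_light":
        out = (np.power(img.astype(np.float64) / 255.0, gamma) * gain) * 255.0
        return np.clip(out, 0, 255).astype(np.uint8)
    if condition == "rain":
        rng = np.random.default_rng(seed)
        h, w = img.shape[:2]
        out = img.astype(np.float64)
        base_angle = math.radians(streak_angle_deg)
        for _ in range(n_streaks):
            x0 = rng.uniform(0, w - 1)
            y0 = rng.uniform(0, h - 1)
            length = rng.uniform(12, 35)
            ang = base_angle + rng.normal(0.0, 0.05)
            x1 = x0 + length * math.sin(ang)
            y1 = y0 + length * math.cos(ang)
            rr, cc = draw_line(int(round(y0)), int(round(x0)),
                               int(round(min(max(y1, 0), h - 1))),
                               int(round(min(max(x1, 0), w - 1))))
            shade = rng.uniform(150, 205)
            alpha = rng.uniform(0.25, 0.45)
            out[rr, cc] = (1 - alpha) * out[rr, cc] + alpha * shade
        out = ndimage.gaussian_filter(out, sigma=(0.5, 0.5, 0.0)) * 0.92
        return np.clip(out, 0, 255).astype(np.uint8)
    raise ConfigError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")


def scene_batch(n: int, base_seed: int = 0, angle_range: tuple[float, float] = (80.0, 100.0),
                gap: bool = False, **overrides) -> list[SceneSpec]:
    """Specs for ``n`` scenes with angles spread over ``angle_range``.

    Scene ``i`` gets seed ``base_seed + i`` and a deterministic angle from
    an evenly spaced grid; with ``gap=True`` each scene carries a center
    seedling-absence gap.
    """
    angles = np.linspace(angle_range[0], angle_range[1], max(n, 1))
    specs = []
    for i in range(n):
        spec = SceneSpec(center_angle_deg=float(angles[i]), seed=base_seed + i, **overrides)
        if gap:
            spec = spec.with_gap()
        specs.append(spec)
    return specs
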