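"""Vegetation segmentation: ExG grayscale, scaled Otsu, NZPR morphology.

The preprocessing stage turns an RGB field image into a near-noiseless
binary crop mask.  Vegetation is enhanced with the excess green index
(ExG = 2g - r - b on channel-normalized RGB), thresholded with a scaled
Otsu threshold, and cleaned with a morphological opening whose iteration
count adapts to the non-zero pixel ratio (NZPR) — the package's proxy for
canopy density / growth stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from PIL import Image
from scipy import ndimage

from .errors import ConfigError, InvalidInputError

_KERNEL3 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class MorphSchedule:
    """Erosion/dilation iteration counts for the adaptive opening.

    Always ``n_dilation = n_erosion // 2`` with a fixed 3x3 kernel.
    """

    n_erosion: int
    n_dilation: int
    kernel_size: int = 3


def exg_grayscale(img: np.ndarray) -> np.ndarray:
    """Excess-green grayscale transform.

    Per pixel, with (r, g, b) the RGB channels normalized by their sum,
    the output is 0 where ``2g - r - b < 0``, 255 where it exceeds 1, and
    ``255 * (2g - r - b)`` otherwise.  A black pixel (R+G+B = 0) maps to 0
    (non-vegetation).

    Parameters
    ----------
    img :
        ``(H, W, 3)`` uint8-compatible RGB array.

    Returns
    -------
    ndarray
        ``(H, W)`` uint8 grayscale image.
    """
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3 or img.size == 0:
        raise InvalidInputError(f"expected non-empty (H, W, 3) RGB array, got {img.shape}")
    rgb = img.astype(np.float64)
    total = rgb.sum(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        g2 = np.where(total > 0, (2.0 * rgb[..., 1] - rgb[..., 0] - rgb[..., 2]) / total, 0.0)
    out = np.clip(g2, 0.0, 1.0) * 255.0
    return np.rint(out).astype(np.uint8)


def otsu_threshold(img: np.ndarray) -> int:
    """Otsu's threshold: the gray level maximizing between-class variance.

    Foreground at threshold ``t`` is the level set ``{0..t}``; the
    between-class variance sigma_B^2(t) = P1*(m1-mG)^2 + P2*(m2-mG)^2 is
    maximized over t in [0, 255], ties broken toward the smallest t.  A
    constant image has sigma_B^2 identically zero; its single level is
    returned with a warning.
    """
    img = np.asarray(img)
    if img.size == 0:
        raise InvalidInputError("cannot threshold an empty image")
    hist = np.bincount(img.ravel().astype(np.int64), minlength=256)[:256].astype(np.float64)
    p = hist / hist.sum()
    levels = np.arange(256, dtype=np.float64)
    p1 = np.cumsum(p)
    m_cum = np.cumsum(levels * p)
    m_g = m_cum[-1]
    if np.count_nonzero(hist) <= 1:
        level = int(np.flatnonzero(hist)[0])
        warnings.warn(
            f"constant image: between-class variance is identically zero; returning level {level}",
            stacklevel=2)
        return level
    p2 = 1.0 - p1
    with np.errstate(divide="ignore", invalid="ignore"):
        m1 = m_cum / p1
        m2 = (m_g - m_cum) / p2
    sigma_b = p1 * (m1 - m_g) ** 2 + p2 * (m2 - m_g) ** 2
    sigma_b[~np.isfinite(sigma_b)] = 0.0
    return int(np.argmax(sigma_b))  # argmax returns the first (smallest) maximizer


def binarize(img: np.ndarray, t_star: int, k: float = 0.8) -> np.ndarray:
    """Binarize at the scaled threshold: 255 iff ``gray > k * t_star``.

    ``k`` is the proportion coefficient (default 0.8) that pulls the
    threshold below the raw Otsu value to keep faint green features.
    """
    if not (0.0 < k <= 1.0):
        raise ConfigError(f"k must be in (0, 1], got {k}")
    img = np.asarray(img)
    return np.where(img > k * t_star, 255, 0).astype(np.uint8)


def compute_nzpr(img: np.ndarray) -> float:
    """Non-zero pixel ratio: foreground fraction of a binary image, in [0, 1]."""
    img = np.asarray(img)
    if img.size == 0:
        return 0.0
    return float((img.astype(np.float64) / 255.0).sum() / img.size)


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def morph_schedule(nzpr: float, resolution: tuple[int, int]) -> MorphSchedule:
    """Erosion/dilation iteration counts as a function of NZPR.

    NZPR enters the polynomials as a fraction in [0, 1].  The piecewise
    models were calibrated separately for the two working resolutions;
    below 6% foreground there are too few feature pixels to erode.
    """
    if not (0.0 <= nzpr <= 1.0):
        raise ConfigError(f"nzpr must be in [0, 1], got {nzpr}")
    resolution = tuple(resolution)
    if resolution == (640, 480):
        if nzpr < 0.06:
            n_ero = 0
        elif nzpr <= 0.50:
            n_ero = _round_half_away(-4.0229 * nzpr**2 + 11.7543 * nzpr - 0.17)
        else:
            n_ero = 5
    elif resolution == (1920, 1080):
        if nzpr < 0.06:
            n_ero = 0
        elif nzpr <= 0.20:
            n_ero = _round_half_away(53.5714 * nzpr**2 + 3.9286 * nzpr + 0.0714)
        elif nzpr <= 0.50:
            n_ero = _round_half_away(10.0 * nzpr + 2.0)
        else:
            n_ero = 8
    else:
        raise ConfigError(f"unsupported resolution {resolution}")
    return MorphSchedule(n_erosion=n_ero, n_dilation=n_ero // 2)


def apply_opening(img: np.ndarray, sched: MorphSchedule) -> np.ndarray:
    """Opening: ``n_erosion`` 3x3 erosions then ``n_dilation`` 3x3 dilations.

    A zero-erosion schedule returns the input unchanged.
    """
    img = np.asarray(img)
    if sched.n_erosion == 0:
        return img.copy()
    fg = img > 0
    fg = ndimage.binary_erosion(fg, structure=_KERNEL3, iterations=sched.n_erosion)
    if sched.n_dilation > 0:
        fg = ndimage.binary_dilation(fg, structure=_KERNEL3, iterations=sched.n_dilation)
    return np.where(fg, 255, 0).astype(np.uint8)


def resize_image(img: np.ndarray, resolution: tuple[int, int],
                 letterbox: bool = False) -> np.ndarray:
    """Resize an RGB image to the working resolution (bilinear).

    By default each axis is resized independently (a 4:3 capture is
    stretched onto a 16:9 target).  With ``letterbox=True`` the aspect
    ratio is preserved and the frame padded with black.
    """
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise InvalidInputError(f"expected (H, W, 3) RGB array, got {img.shape}")
    w, h = resolution
    if img.shape[0] == h and img.shape[1] == w:
        return img
    pil = Image.fromarray(img.astype(np.uint8))
    if not letterbox:
        return np.asarray(pil.resize((w, h), Image.BILINEAR))
    scale = min(w / img.shape[1], h / img.shape[0])
    new_w = max(1, int(round(img.shape[1] * scale)))
    new_h = max(1, int(round(img.shape[0] * scale)))
    resized = np.asarray(pil.resize((new_w, new_h), Image.BILINEAR))
    out = np.zeros((h, w, 3), dtype=np.uint8)
    y0 = (h - new_h) // 2
    x0 = (w - new_w) // 2
    out[y0:y0 + new_h, x0:x0 + new_w] = resized
    return out


def preprocess(img: np.ndarray, cfg) -> tuple[np.ndarray, dict]:
    """Full preprocessing: ExG -> Otsu -> scaled binarization -> opening.

    Returns the cleaned binary mask and a diagnostics dict (threshold,
    whole-image NZPR, schedule).
    """
    gray = exg_grayscale(img)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t_star = otsu_threshold(gray)
    binary = binarize(gray, t_star, k=cfg.k_otsu)
    nzpr = compute_nzpr(binary)
    if cfg.morphology_enabled:
        sched = morph_schedule(nzpr, cfg.resolution)
    else:
        sched = MorphSchedule(0, 0)
    opened = apply_opening(binary, sched)
    diag = {
        "otsu_threshold": t_star,
        "nzpr": nzpr,
        "n_erosion": sched.n_erosion,
        "n_dilation": sched.n_dilation,
    }
    return opened, diag
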