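"""Leaf morphometrics: the 15 leaf traits from an RGB image plus binary mask.

Size traits (area, perimeter, length, width) are measured on the mask; shape
indices are arithmetic combinations of the size traits; color traits are
masked channel means. Lobe count is supplied by the caller (it is counted
manually in the field protocol this package models) and is never inferred
from the image.

Measurement conventions
-----------------------
* area — foreground pixel count times the squared pixel scale.
* perimeter — sub-pixel outline length: the mask is lightly smoothed and the
  0.5 iso-contour traced marching-squares style, then measured as a polyline.
  Counting boundary pixels instead would overestimate the perimeter of smooth
  outlines by roughly 8-10% and bias circularity downward.
* length / width — extents of the foreground pixels projected onto the first
  and second principal axes of their coordinates (the oriented bounding box),
  with one pixel added for the pixel footprint; width <= length by ordering.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
from scipy import ndimage
from skimage import measure as _skmeasure
from skimage.filters import gaussian as _gaussian

from .core_io import ValidationError

__all__ = [
    "measure_size",
    "derive_shape",
    "measure_color",
    "measure_leaf",
    "SHAPE_TRAITS",
]

SHAPE_TRAITS = ("AR", "P_L", "P_LW", "Rect", "Cir")

#: Gaussian sigma (px) used to smooth the mask before contour tracing.
_CONTOUR_SIGMA = 2.0


def _single_component(mask: np.ndarray) -> np.ndarray:
    """Hole-fill the mask and require exactly one connected component."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValidationError("empty mask")
    filled = ndimage.binary_fill_holes(mask)
    labels, n = _skmeasure.label(filled, return_num=True, connectivity=2)
    if n > 1:
        sizes = np.bincount(labels.ravel())[1:]
        raise ValidationError(
            f"mask has {n} connected components (sizes {sorted(sizes, reverse=True)[:5]}); "
            "expected exactly one"
        )
    return filled


def _contour_perimeter_px(filled: np.ndarray) -> float:
    """Sub-pixel outline length of the (single) foreground region, in pixels."""
    pad = int(np.ceil(3 * _CONTOUR_SIGMA)) + 1
    padded = np.pad(filled.astype(float), pad)
    smooth = _gaussian(padded, sigma=_CONTOUR_SIGMA, preserve_range=True)
    contours = _skmeasure.find_contours(smooth, 0.5)
    if not contours:  # degenerate: region thinner than the smoothing kernel
        contours = _skmeasure.find_contours(padded, 0.5)
    outline = max(contours, key=len)
    diffs = np.diff(outline, axis=0, append=outline[:1])
    return float(np.sum(np.hypot(diffs[:, 0], diffs[:, 1])))


def _principal_extents_px(filled: np.ndarray) -> tuple[float, float]:
    """Extents of pixel centers on the two principal axes, plus 1 px footprint."""
    coords = np.argwhere(filled).astype(float)
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / len(centered)
    _, vecs = np.linalg.eigh(cov)  # ascending eigenvalues
    proj = centered @ vecs
    ext_minor = proj[:, 0].max() - proj[:, 0].min() + 1.0
    ext_major = proj[:, 1].max() - proj[:, 1].min() + 1.0
    if ext_minor > ext_major:
        ext_major, ext_minor = ext_minor, ext_major
    return float(ext_major), float(ext_minor)


def measure_size(mask: np.ndarray, pixel_scale: float) -> tuple[float, float, float, float]:
    """Leaf area (cm²), perimeter, length and width (cm) from a binary mask.

    Raises on an empty mask, more than one connected component, or a
    non-positive pixel scale. Width never exceeds length.
    """
    if pixel_scale <= 0:
        raise ValidationError("pixel_scale must be > 0")
    filled = _single_component(mask)
    la = float(filled.sum()) * pixel_scale**2
    lp = _contour_perimeter_px(filled) * pixel_scale
    ll_px, lw_px = _principal_extents_px(filled)
    return la, lp, ll_px * pixel_scale, lw_px * pixel_scale


def derive_shape(
    la: float, lp: float, ll: float, lw: float, llo: int | None = None
) -> tuple[float, float, float, float, float]:
    """Shape indices from the size primitives.

    Returns ``(AR, P_L, P_LW, Rect, Cir)`` where AR = LL/LW, P_L = LP/LL,
    P_LW = LP/(LL+LW), Rect = LA/(LL·LW) (fill fraction of the oriented
    bounding rectangle), and Cir = 4π·LA/LP² (1 for a disc). ``llo`` is
    accepted for interface symmetry; lobe count feeds no derived index.
    """
    for name, v in (("LA", la), ("LP", lp), ("LL", ll), ("LW", lw)):
        if not np.isfinite(v) or v <= 0:
            raise ValidationError(f"{name} must be a positive finite number, got {v}")
    ar = ll / lw
    p_l = lp / ll
    p_lw = lp / (ll + lw)
    rect = la / (ll * lw)
    cir = 4.0 * np.pi * la / lp**2
    return ar, p_l, p_lw, rect, cir


def measure_color(image: np.ndarray, mask: np.ndarray) -> tuple[float, float, float, float]:
    """Masked RGB channel means and the composite color value.

    The composite is ``CV = 65536·R + 256·G + B`` evaluated on the (possibly
    fractional) channel means, so it ranges over [0, 16 777 215].
    """
    image = np.asarray(image)
    mask = np.asarray(mask, dtype=bool)
    if image.shape[:2] != mask.shape:
        raise ValidationError(
            f"image {image.shape[:2]} and mask {mask.shape} dimensions differ"
        )
    if image.ndim != 3 or image.shape[2] < 3:
        raise ValidationError("image must be H x W x 3 (RGB)")
    if not mask.any():
        raise ValidationError("empty mask")
    fg = image[mask].astype(float)
    r, g, b = fg[:, 0].mean(), fg[:, 1].mean(), fg[:, 2].mean()
    cv = 65536.0 * r + 256.0 * g + b
    return float(r), float(g), float(b), float(cv)


def measure_leaf(
    image: np.ndarray, mask: np.ndarray, pixel_scale: float, lobe_count: int
) -> Mapping[str, float]:
    """All 14 quantitative leaf traits for one leaf, keyed by trait name."""
    la, lp, ll, lw = measure_size(mask, pixel_scale)
    ar, p_l, p_lw, rect, cir = derive_shape(la, lp, ll, lw)
    r, g, b, cv = measure_color(image, mask)
    return {
        "LA": la, "LP": lp, "LL": ll, "LW": lw, "LLo": float(lobe_count),
        "AR": ar, "P_L": p_l, "P_LW": p_lw, "Rect": rect, "Cir": cir,
        "R": r, "G": g, "B": b, "CV": cv,
    }
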