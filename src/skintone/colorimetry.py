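"""sRGB ↔ CIELAB conversion and the Individual Typology Angle (ITA).

The ITA is a continuous colorimetric measure of constitutive skin pigmentation,

    ITA = arctan((L* − 50) / b*) · 180 / π   [degrees]

computed from the CIELAB lightness L* and the blue–yellow chromaticity b* of
skin pixels.  Higher ITA means lighter skin.  All conversions assume
gamma-encoded 8-bit sRGB input (IEC 61966-2-1 transfer function), a D65
illuminant and the 2° standard observer — the universal defaults for consumer
digital images.

Functions are vectorised: colors may be single triples, ``(n, 3)`` pixel
lists, or ``(h, w, 3)`` images.
"""

from __future__ import annotations

import warnings

import numpy as np
from skimage import color as _skcolor

__all__ = [
    "srgb_to_lab",
    "lab_to_srgb",
    "ita_from_lab",
    "ita_from_srgb",
    "region_ita",
    "EmptyRegionError",
]


class EmptyRegionError(ValueError):
    """Raised when an ITA is requested for a region with no pixels."""


def _as_rgb_array(rgb) -> np.ndarray:
    arr = np.asarray(rgb)
    if arr.shape[-1] != 3:
        raise ValueError(f"expected trailing RGB axis of length 3, got shape {arr.shape}")
    if np.issubdtype(arr.dtype, np.floating) and not np.all(arr == np.round(arr)):
        raise ValueError("RGB channels must be 8-bit integers in [0, 255]")
    arr = arr.astype(np.float64)
    if arr.size and (arr.min() < 0 or arr.max() > 255):
        raise ValueError("RGB channel out of range [0, 255]")
    return arr


def srgb_to_lab(rgb) -> np.ndarray:
    """Convert 8-bit sRGB colors to CIELAB (D65, 2° observer).

    Parameters
    ----------
    rgb : array-like, shape (..., 3)
        Integer channel values in [0, 255].

    Returns
    -------
    ndarray, shape (..., 3)
        ``L*`` in [0, 100], ``a*`` and ``b*`` unbounded (typically within
        ±128).
    """
    arr = _as_rgb_array(rgb) / 255.0
    lab = _skcolor.rgb2lab(arr.reshape(1, -1, 3)).reshape(arr.shape)
    return lab


def lab_to_srgb(lab) -> np.ndarray:
    """Convert CIELAB to 8-bit sRGB, clipping out-of-gamut values."""
    arr = np.asarray(lab, dtype=np.float64)
    if arr.shape[-1] != 3:
        raise ValueError(f"expected trailing Lab axis of length 3, got shape {arr.shape}")
    with warnings.catch_warnings():
        # out-of-gamut colors are clipped by design
        warnings.filterwarnings("ignore", message=".*negative Z values.*")
        rgb = _skcolor.lab2rgb(arr.reshape(1, -1, 3)).reshape(arr.shape)
    return np.clip(np.round(rgb * 255.0), 0, 255).astype(np.uint8)


def ita_from_lab(lab) -> np.ndarray | float:
    """Individual Typology Angle, in degrees, from CIELAB.

    Uses the quadrant-aware two-argument arctangent of ``(L* − 50, b*)``,
    clamped to [−90, 90], so the function is total: ``b* = 0`` yields ±90°
    depending on the sign of ``L* − 50``, and ``L* = 50`` yields 0° for any
    ``b*``.  For physiological skin colors (``b* > 0``) this coincides with
    the plain ``arctan((L*−50)/b*)`` formula.
    """
    arr = np.asarray(lab, dtype=np.float64)
    scalar = arr.ndim == 1
    arr = np.atleast_2d(arr)
    num = arr[..., 0] - 50.0
    ita = np.degrees(np.arctan2(num, arr[..., 2]))
    ita = np.where(num == 0.0, 0.0, ita)
    ita = np.clip(ita, -90.0, 90.0)
    return float(ita[0]) if scalar else ita


def ita_from_srgb(rgb) -> np.ndarray | float:
    """ITA of 8-bit sRGB colors (convenience composition)."""
    return ita_from_lab(srgb_to_lab(rgb))


def region_ita(pixels, method: str = "mean_of_itas") -> float:
    """Aggregate the ITA of a pixel region into a single angle.

    Parameters
    ----------
    pixels : array-like, shape (n, 3)
        8-bit sRGB pixel values of the region.
    method : {"mean_of_itas", "ita_of_mean_lab"}
        ``mean_of_itas`` (default) averages per-pixel ITA values;
        ``ita_of_mean_lab`` takes the ITA of the channel-wise mean Lab color.
        The two agree for homogeneous regions and differ slightly under
        noise because arctan is nonlinear.

    Raises
    ------
    EmptyRegionError
        If the region contains no pixels.  Exclusion policy is the caller's.
    """
    arr = _as_rgb_array(pixels).reshape(-1, 3)
    if arr.shape[0] == 0:
        raise EmptyRegionError("region contains no pixels")
    lab = srgb_to_lab(arr.astype(np.uint8))
    if method == "mean_of_itas":
        return float(np.mean(ita_from_lab(lab)))
    if method == "ita_of_mean_lab":
        return float(ita_from_lab(lab.mean(axis=0)))
    raise ValueError(f"unknown aggregation method: {method!r}")
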