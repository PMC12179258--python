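"""Pixel extraction for the sampled body regions.

Two regions are sampled: the lower arms, identified by part labels 19 and 20
of a dense-pose body-part label map (the IUV part convention), and the nasal
bridge, identified by points 27–30 of the standard 68-point facial-landmark
scheme.  The nasal bridge is a good facial sampling site because it is
central, rarely covered by hair or makeup, and usually evenly lit.

The module consumes annotation *outputs* (label-map PNGs, landmark CSVs)
produced by any detector; it never runs the neural models itself.
Coordinates are 0-based, x right, y down; landmark coordinates are rounded
half-up to the nearest pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "ARM_PART_LABELS",
    "NASAL_BRIDGE_LANDMARKS",
    "LandmarkSet",
    "RegionSample",
    "load_image",
    "load_part_map",
    "load_landmarks",
    "extract_arm_pixels",
    "extract_face_pixels",
]

ARM_PART_LABELS = (19, 20)  # left / right lower arm in the IUV part convention
NASAL_BRIDGE_LANDMARKS = (27, 28, 29, 30)
N_LANDMARKS = 68


@dataclass(frozen=True)
class LandmarkSet:
    """68 facial landmark coordinates, optionally with per-point confidence."""

    points: np.ndarray  # (68, 2) float, (x, y)
    confidence: np.ndarray | None = None

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.shape != (N_LANDMARKS, 2):
            raise ValueError(f"expected ({N_LANDMARKS}, 2) landmark array, got {pts.shape}")
        object.__setattr__(self, "points", pts)


@dataclass(frozen=True)
class RegionSample:
    """The pixel set extracted for one body region of one image."""

    region: str  # "arm" | "face"
    pixels: np.ndarray  # (n, 3) uint8 sRGB, row-major image order
    provenance: dict = field(default_factory=dict)
    reason: str = ""  # nonempty iff extraction failed / region absent

    @property
    def pixel_count(self) -> int:
        return int(self.pixels.shape[0])


def load_image(path) -> np.ndarray:
    """Read an RGB image as an (h, w, 3) uint8 array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def load_part_map(path) -> np.ndarray:
    """Read a single-channel integer part-label PNG as an (h, w) array."""
    with Image.open(path) as im:
        arr = np.asarray(im)
    if arr.ndim == 3:  # tolerate label maps saved with redundant channels
        arr = arr[..., 0]
    return arr.astype(np.int64)


def load_landmarks(path) -> LandmarkSet:
    """Read landmarks from CSV: either ``index,x,y[,confidence]`` rows or the
    OpenFace wide dialect with ``x_0..x_67`` / ``y_0..y_67`` columns."""
    df = pd.read_csv(path)
    df.columns = [c.strip() for c in df.columns]
    if "x_0" in df.columns:  # OpenFace wide format, one row per face
        row = df.iloc[0]
        pts = np.array([[row[f"x_{i}"], row[f"y_{i}"]] for i in range(N_LANDMARKS)], dtype=np.float64)
        conf = np.full(N_LANDMARKS, float(row["confidence"])) if "confidence" in df.columns else None
        return LandmarkSet(points=pts, confidence=conf)
    df = df.sort_values("index")
    if len(df) != N_LANDMARKS:
        raise ValueError(f"expected {N_LANDMARKS} landmark rows, got {len(df)}")
    pts = df[["x", "y"]].to_numpy(dtype=np.float64)
    conf = df["confidence"].to_numpy(dtype=np.float64) if "confidence" in df.columns else None
    return LandmarkSet(points=pts, confidence=conf)


def extract_arm_pixels(image: np.ndarray, parts: np.ndarray, labels=ARM_PART_LABELS) -> RegionSample:
    """All and only pixels whose part label is a lower-arm label (19 or 20).

    Pixels are returned in row-major image order.  Zero matching pixels is
    not an error: the sample comes back empty and the pipeline decides
    whether to exclude the image.
    """
    image = np.asarray(image)
    parts = np.asarray(parts)
    if image.shape[:2] != parts.shape:
        raise ValueError(f"image {image.shape[:2]} and label map {parts.shape} dimensions differ")
    mask = np.isin(parts, labels)
    pixels = image[mask].reshape(-1, 3).astype(np.uint8)
    provenance = {f"label_{lab}": int((parts == lab).sum()) for lab in labels}
    reason = "" if pixels.shape[0] else "no_region"
    return RegionSample(region="arm", pixels=pixels, provenance=provenance, reason=reason)


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(np.asarray(x, dtype=np.float64) + 0.5).astype(np.int64)


def extract_face_pixels(
    image: np.ndarray, landmarks: LandmarkSet, radius: int = 0
) -> RegionSample:
    """Nasal-bridge pixels at landmarks 27–30.

    With ``radius`` 0 (default) exactly the four landmark pixels are sampled;
    with radius r, the union of their (2r+1)² neighborhoods, clipped to the
    image and deduplicated.  Any nasal-bridge landmark out of frame yields an
    empty sample with the reason recorded.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    image = np.asarray(image)
    h, w = image.shape[:2]
    pts = _round_half_up(landmarks.points[list(NASAL_BRIDGE_LANDMARKS)])
    out = (pts[:, 0] < 0) | (pts[:, 0] >= w) | (pts[:, 1] < 0) | (pts[:, 1] >= h)
    provenance = {"landmarks": list(NASAL_BRIDGE_LANDMARKS), "radius": radius}
    if out.any():
        missing = [int(NASAL_BRIDGE_LANDMARKS[i]) for i in np.flatnonzero(out)]
        return RegionSample(
            region="face",
            pixels=np.empty((0, 3), dtype=np.uint8),
            provenance=provenance,
            reason=f"landmarks_out_of_frame:{missing}",
        )
    offs = np.arange(-radius, radius + 1)
    dx, dy = np.meshgrid(offs, offs)
    xs = (pts[:, 0][:, None] + dx.ravel()[None, :]).ravel()
    ys = (pts[:, 1][:, None] + dy.ravel()[None, :]).ravel()
    keep = (xs >= 0) & (xs < w) & (ys >= 0) & (ys < h)
    coords = np.unique(np.stack([ys[keep], xs[keep]], axis=1), axis=0)  # row-major order
    pixels = image[coords[:, 0], coords[:, 1]].astype(np.uint8)
    return RegionSample(region="face", pixels=pixels, provenance=provenance, reason="")
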