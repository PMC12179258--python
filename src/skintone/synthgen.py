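"""Synthetic cohorts with known colorimetric ground truth.

Generates simple frontal "body" images — two lower-arm rectangles carrying
part labels 19/20 and a face block with nasal-bridge landmarks 27–30 — whose
skin color is drawn from a Monk reference swatch plus Gaussian noise in Lab.
Because the gold Lab color, ITA and Monk class of every record are known
exactly, the extraction → colorimetry → classification → evaluation chain
can be tested end to end without any real images.

The generator emulates the standardized-lighting, one-person-per-image
character of AI-generated validation cohorts; an optional multiplicative L*
ramp mimics uneven illumination.  A configurable fraction of records omits
the arm rectangles to exercise the pipeline's exclusion path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .colorimetry import ita_from_lab, lab_to_srgb, srgb_to_lab
from .regions import ARM_PART_LABELS, N_LANDMARKS, NASAL_BRIDGE_LANDMARKS, LandmarkSet
from .scales import ReferencePalette, derive_thresholds, monk_palette

__all__ = ["SyntheticSpec", "SyntheticRecord", "make_patch", "make_cohort", "write_cohort"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic validation cohort.

    ``class_weights`` is the sampling distribution over the palette's tone
    classes (uniform by default); ``sigma`` is the per-channel Gaussian noise
    in Lab units; ``lighting_amplitude`` scales a vertical multiplicative L*
    ramp (0 = flat lighting); ``armless_fraction`` of images get no arm
    rectangles, exercising the no-region exclusion path.
    """

    n_images: int = 100
    seed: int = 0
    sigma: float = 2.0
    class_weights: tuple | None = None
    lighting_amplitude: float = 0.0
    armless_fraction: float = 0.0
    image_size: tuple = (160, 120)  # (height, width)

    def __post_init__(self):
        if self.n_images < 1:
            raise ValueError("n_images must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not 0 <= self.armless_fraction <= 1:
            raise ValueError("armless_fraction must be in [0, 1]")
        if self.class_weights is not None:
            w = np.asarray(self.class_weights, dtype=np.float64)
            if w.min() < 0 or w.sum() <= 0:
                raise ValueError("class weights must be nonnegative with a positive sum")


@dataclass
class SyntheticRecord:
    """One synthetic image with its annotations and colorimetric gold truth."""

    image_id: str
    image: np.ndarray          # (h, w, 3) uint8
    parts: np.ndarray          # (h, w) uint8 part labels (19/20 = arms)
    landmarks: LandmarkSet
    gold_class: int            # Monk tone 1..10 (or palette class)
    gold_lab: np.ndarray       # the noiseless class centroid Lab
    gold_ita: float            # ita_from_lab(gold_lab)


def make_patch(lab, size, sigma: float, rng) -> np.ndarray:
    """A ``size = (h, w)`` sRGB patch of ``lab`` plus Gaussian Lab noise.

    Out-of-gamut colors are clipped on conversion; a gamut warning is issued
    when the clipping moves the mean noticeably.
    """
    h, w = size
    lab = np.asarray(lab, dtype=np.float64)
    noisy = lab[None, None, :] + (rng.normal(0.0, sigma, size=(h, w, 3)) if sigma > 0 else 0.0)
    rgb = lab_to_srgb(noisy if sigma > 0 else np.broadcast_to(noisy, (h, w, 3)))
    back = srgb_to_lab(rgb).reshape(-1, 3).mean(axis=0)
    if np.any(np.abs(back - lab) > max(3 * sigma, 2.5)):
        warnings.warn(f"Lab {lab.tolist()} is far outside the sRGB gamut; patch mean shifted")
    return rgb


def _layout(shape):
    """Pixel geometry of the synthetic body: face block and two arm boxes."""
    h, w = shape
    face = (slice(h // 10, h // 10 + h // 5), slice(w // 2 - w // 8, w // 2 + w // 8))
    arm_h = slice(h // 2, h // 2 + h // 3)
    left_arm = (arm_h, slice(w // 12, w // 12 + w // 6))
    right_arm = (arm_h, slice(w - w // 12 - w // 6, w - w // 12))
    return face, left_arm, right_arm


def _nasal_bridge_landmarks(face_slices, shape) -> LandmarkSet:
    """All 68 points placed inside the face block; 27–30 run down its center."""
    rows, cols = face_slices
    cx = (cols.start + cols.stop - 1) / 2
    pts = np.column_stack(
        [
            np.full(N_LANDMARKS, cx),
            np.linspace(rows.start + 1, rows.stop - 2, N_LANDMARKS),
        ]
    )
    top, bottom = rows.start + 2, rows.start + (rows.stop - rows.start) // 2
    for i, lm in enumerate(NASAL_BRIDGE_LANDMARKS):
        pts[lm] = (cx, top + i * max((bottom - top) // 3, 1))
    return LandmarkSet(points=pts)


def make_cohort(spec: SyntheticSpec, palette: ReferencePalette | None = None):
    """Generate a cohort of synthetic records plus the gold annotation table.

    Returns ``(records, gold)`` where gold is a DataFrame with one row per
    image and region (columns image_id, region, scale, class, gold_ita,
    image_type) matching the evaluation module's gold-table contract.
    """
    palette = palette or monk_palette()
    scale = derive_thresholds(palette)
    rng = np.random.default_rng(spec.seed)
    k = len(palette.labels)
    weights = (
        np.full(k, 1.0 / k)
        if spec.class_weights is None
        else np.asarray(spec.class_weights, float) / np.sum(spec.class_weights)
    )
    h, w = spec.image_size
    face_sl, left_sl, right_sl = _layout((h, w))
    landmarks = _nasal_bridge_landmarks(face_sl, (h, w))
    # exactly round(fraction * n) records omit arms, chosen at random
    n_armless = round(spec.armless_fraction * spec.n_images)
    armless = np.zeros(spec.n_images, dtype=bool)
    armless[rng.choice(spec.n_images, n_armless, replace=False)] = True

    records, gold_rows = [], []
    for i in range(spec.n_images):
        cls = int(rng.choice(k, p=weights)) + 1
        centroid = palette.lab[cls - 1]
        gold_ita = float(ita_from_lab(centroid))

        image = np.full((h, w, 3), 190, dtype=np.uint8)  # neutral backdrop
        parts = np.zeros((h, w), dtype=np.uint8)

        def paint(slices):
            sh = (slices[0].stop - slices[0].start, slices[1].stop - slices[1].start)
            image[slices] = make_patch(centroid, sh, spec.sigma, rng)

        paint(face_sl)
        if not armless[i]:
            paint(left_sl)
            paint(right_sl)
            parts[left_sl] = ARM_PART_LABELS[0]
            parts[right_sl] = ARM_PART_LABELS[1]

        if spec.lighting_amplitude > 0:
            lab_img = srgb_to_lab(image)
            ramp = 1.0 + spec.lighting_amplitude * (np.linspace(-0.5, 0.5, h))[:, None]
            lab_img[..., 0] = np.clip(lab_img[..., 0] * ramp, 0, 100)
            image = lab_to_srgb(lab_img)

        image_id = f"synth_{i:04d}"
        records.append(
            SyntheticRecord(
                image_id=image_id,
                image=image,
                parts=parts,
                landmarks=landmarks,
                gold_class=cls,
                gold_lab=np.asarray(centroid, float),
                gold_ita=gold_ita,
            )
        )
        for region in ("arm", "face"):
            gold_rows.append(
                {
                    "image_id": image_id,
                    "region": region,
                    "scale": scale.name,
                    "class": cls,
                    "gold_ita": gold_ita,
                    "image_type": "generated",
                }
            )
    return records, pd.DataFrame(gold_rows)


def write_cohort(records, gold: pd.DataFrame, outdir) -> None:
    """Write a cohort to disk: PNG images + label maps, landmark CSVs, gold.csv."""
    outdir = Path(outdir)
    for sub in ("images", "parts", "landmarks"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)
    for rec in records:
        Image.fromarray(rec.image).save(outdir / "images" / f"{rec.image_id}.png")
        Image.fromarray(rec.parts).save(outdir / "parts" / f"{rec.image_id}.png")
        pd.DataFrame(
            {
                "index": np.arange(N_LANDMARKS),
                "x": rec.landmarks.points[:, 0],
                "y": rec.landmarks.points[:, 1],
            }
        ).to_csv(outdir / "landmarks" / f"{rec.image_id}.csv", index=False)
    gold.to_csv(outdir / "gold.csv", index=False)
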