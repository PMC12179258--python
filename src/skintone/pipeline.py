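"""Per-image orchestration and batch runs.

For each image: extract the arm and/or face pixel sets from the supplied
annotations, aggregate each region's ITA, classify it on every configured
scale, and record exclusions (no detectable region, too few arm pixels)
instead of failing.  The per-image mean ITA of a region is the skin tone
measurement for that image.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .colorimetry import region_ita
from .regions import (
    RegionSample,
    extract_arm_pixels,
    extract_face_pixels,
    load_image,
    load_landmarks,
    load_part_map,
)
from .scales import SkinToneScale, derive_thresholds, fitzpatrick_scale, load_palette, monk_scale

__all__ = ["RunConfig", "RegionResult", "ImageResult", "process_image", "run_batch", "results_to_frame"]

log = logging.getLogger(__name__)

RESULTS_SCHEMA_VERSION = 1
RESULT_COLUMNS = ["image_id", "region", "pixel_count", "mean_ita", "monk", "fitzpatrick", "exclusion_reason"]


@dataclass(frozen=True)
class RunConfig:
    """Everything a batch run needs to be reproducible."""

    aggregation: str = "mean_of_itas"  # or "ita_of_mean_lab"
    face_radius: int = 0
    min_arm_pixels: int = 50
    scales: tuple = ("monk", "fitzpatrick")
    palette_path: str | None = None       # override the bundled Monk palette
    fitzpatrick_config: str | None = None  # JSON with {"boundaries": [...]}
    exclude_ids: tuple = ()                # human-flagged images (erythema, tattoos)
    seed: int = 0

    def build_scales(self) -> dict[str, SkinToneScale]:
        out: dict[str, SkinToneScale] = {}
        if "monk" in self.scales:
            out["monk"] = (
                derive_thresholds(load_palette(self.palette_path))
                if self.palette_path
                else monk_scale()
            )
        if "fitzpatrick" in self.scales:
            if self.fitzpatrick_config:
                doc = json.loads(Path(self.fitzpatrick_config).read_text())
                out["fitzpatrick"] = fitzpatrick_scale(tuple(doc["boundaries"]))
            else:
                out["fitzpatrick"] = fitzpatrick_scale()
        return out

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        doc = json.loads(Path(path).read_text())
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("scales", "exclude_ids"):
            if key in doc:
                doc[key] = tuple(doc[key])
        return cls(**doc)


@dataclass
class RegionResult:
    region: str
    pixel_count: int = 0
    mean_ita: float | None = None
    classes: dict = field(default_factory=dict)  # scale name -> class index 1..K
    exclusion_reason: str = ""


@dataclass
class ImageResult:
    image_id: str
    regions: dict = field(default_factory=dict)  # region name -> RegionResult
    error: str = ""


def _classify_region(sample: RegionSample, scales, config: RunConfig) -> RegionResult:
    res = RegionResult(region=sample.region, pixel_count=sample.pixel_count)
    if sample.reason:
        res.exclusion_reason = "no_region" if sample.pixel_count == 0 else sample.reason
        return res
    if sample.region == "arm" and sample.pixel_count < config.min_arm_pixels:
        res.exclusion_reason = "below_min_pixels"
        return res
    res.mean_ita = region_ita(sample.pixels, method=config.aggregation)
    res.classes = {name: scale.classify_index(res.mean_ita) for name, scale in scales.items()}
    return res


def process_image(
    image: np.ndarray,
    image_id: str,
    config: RunConfig,
    parts: np.ndarray | None = None,
    landmarks=None,
    scales: dict[str, SkinToneScale] | None = None,
) -> ImageResult:
    """Measure and classify one image's regions; flag unusable regions.

    At least one of ``parts`` (body-part label map) and ``landmarks`` (facial
    landmark set) must be given.  Regions without usable pixels come back
    with an exclusion reason, never as a silent drop.
    """
    if parts is None and landmarks is None:
        raise ValueError("annotations must include a part label map or landmarks")
    scales = scales or config.build_scales()
    result = ImageResult(image_id=image_id)
    if image_id in config.exclude_ids:
        for region in ("arm", "face"):
            result.regions[region] = RegionResult(region=region, exclusion_reason="human_excluded")
        return result
    if parts is not None:
        sample = extract_arm_pixels(image, parts)
        result.regions["arm"] = _classify_region(sample, scales, config)
    if landmarks is not None:
        sample = extract_face_pixels(image, landmarks, radius=config.face_radius)
        result.regions["face"] = _classify_region(sample, scales, config)
    return result


def results_to_frame(results: list[ImageResult]) -> pd.DataFrame:
    """Flatten ImageResults to the versioned long-format results table."""
    rows = []
    for r in results:
        if r.error:
            rows.append(
                dict.fromkeys(RESULT_COLUMNS) | {"image_id": r.image_id, "exclusion_reason": f"error:{r.error}"}
            )
            continue
        for region, rr in r.regions.items():
            rows.append(
                {
                    "image_id": r.image_id,
                    "region": region,
                    "pixel_count": rr.pixel_count,
                    "mean_ita": rr.mean_ita,
                    "monk": rr.classes.get("monk"),
                    "fitzpatrick": rr.classes.get("fitzpatrick"),
                    "exclusion_reason": rr.exclusion_reason,
                }
            )
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    df.attrs["schema_version"] = RESULTS_SCHEMA_VERSION
    return df


def run_batch(manifest, config: RunConfig) -> pd.DataFrame:
    """Process a manifest of images into one results table.

    ``manifest`` is an iterable of dicts with keys ``image_id`` and ``image``
    (array or path) plus optional ``parts`` and ``landmarks`` (arrays/objects
    or paths).  Per-image read or processing errors are recorded in the
    table and the run continues.
    """
    manifest = list(manifest)
    if not manifest:
        raise ValueError("manifest is empty")
    scales = config.build_scales()
    results = []
    for entry in manifest:
        image_id = entry["image_id"]
        try:
            image = entry["image"]
            if isinstance(image, (str, Path)):
                image = load_image(image)
            parts = entry.get("parts")
            if isinstance(parts, (str, Path)):
                parts = load_part_map(parts)
            landmarks = entry.get("landmarks")
            if isinstance(landmarks, (str, Path)):
                landmarks = load_landmarks(landmarks)
            results.append(
                process_image(image, image_id, config, parts=parts, landmarks=landmarks, scales=scales)
            )
        except Exception as exc:  # noqa: BLE001 - per-image fault isolation
            log.warning("image %s failed: %s", image_id, exc)
            results.append(ImageResult(image_id=image_id, error=str(exc)))
    df = results_to_frame(results)
    n_excluded = int((df["exclusion_reason"] != "").sum())
    log.info("processed %d images (%d rows, %d exclusions)", len(manifest), len(df), n_excluded)
    return df
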