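"""Skin tone scales: palette calibration and ITA classification.

A scale is an ordered set of K tone classes, class 1 lightest, separated by
K−1 ITA thresholds in strictly descending order.  Thresholds for the Monk
Skin Tone Scale are *derived* from the ten published reference swatches:
the ITA of each swatch is computed, and the boundary between adjacent tones
is the midpoint of their ITAs.  Fitzpatrick cut-offs are taken from the
published ITA band literature (I: >55, II: 41–55, III: 28–41, IV: 10–28,
V: −30–10, VI: ≤−30) and can be overridden from a config file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .colorimetry import ita_from_lab, srgb_to_lab

__all__ = [
    "ReferencePalette",
    "SkinToneScale",
    "ClassAssignment",
    "CalibrationError",
    "derive_thresholds",
    "load_palette",
    "monk_palette",
    "monk_scale",
    "fitzpatrick_scale",
]

# Open outer interval bounds used in serialized tables; classification itself
# treats the outer intervals as unbounded (|ITA| cannot exceed 90).
SENTINEL_HI = 100.0
SENTINEL_LO = -100.0

FITZPATRICK_BOUNDARIES = (55.0, 41.0, 28.0, 10.0, -30.0)
FITZPATRICK_LABELS = ("I", "II", "III", "IV", "V", "VI")


class CalibrationError(ValueError):
    """Palette cannot produce a valid scale (non-monotone swatch ITAs)."""


def _hex_to_rgb(hexstr: str) -> tuple[int, int, int]:
    h = hexstr.lstrip("#")
    return tuple(int(h[i : i + 2], 16) for i in (0, 2, 4))


@dataclass(frozen=True)
class ReferencePalette:
    """An ordered list of reference swatch colors, index 1 = lightest."""

    name: str
    labels: tuple
    lab: np.ndarray  # (K, 3) CIELAB swatch colors

    def __post_init__(self):
        if len(self.labels) < 2:
            raise ValueError("palette needs at least 2 swatches")
        if np.asarray(self.lab).shape != (len(self.labels), 3):
            raise ValueError("lab array must be (K, 3)")

    @property
    def itas(self) -> np.ndarray:
        return np.asarray(ita_from_lab(self.lab))

    @classmethod
    def from_hex(cls, name: str, hexes, labels=None) -> "ReferencePalette":
        rgb = np.array([_hex_to_rgb(h) for h in hexes], dtype=np.uint8)
        labels = tuple(labels) if labels is not None else tuple(range(1, len(hexes) + 1))
        return cls(name=name, labels=labels, lab=srgb_to_lab(rgb))


def load_palette(path) -> ReferencePalette:
    """Read a palette JSON file.

    Accepts either ``{"name": ..., "swatches": [{"label", "hex"|"lab"}, ...]}``
    or a bare JSON array of swatch objects.
    """
    doc = json.loads(Path(path).read_text())
    if isinstance(doc, list):
        doc = {"name": Path(path).stem, "swatches": doc}
    labels, labs = [], []
    for sw in doc["swatches"]:
        labels.append(sw["label"])
        if "hex" in sw:
            labs.append(srgb_to_lab(np.array(_hex_to_rgb(sw["hex"]), dtype=np.uint8)))
        else:
            labs.append(np.asarray(sw["lab"], dtype=np.float64))
    return ReferencePalette(name=doc.get("name", "palette"), labels=tuple(labels), lab=np.vstack(labs))


def monk_palette() -> ReferencePalette:
    """The bundled 10-swatch Monk Skin Tone Scale reference palette."""
    with resources.files("skintone.data").joinpath("monk_palette.json").open() as fh:
        doc = json.load(fh)
    hexes = [sw["hex"] for sw in doc["swatches"]]
    labels = tuple(sw["label"] for sw in doc["swatches"])
    return ReferencePalette.from_hex(doc["name"], hexes, labels)


@dataclass(frozen=True)
class ClassAssignment:
    scale_name: str
    class_index: int  # 1..K
    label: object
    ita: float


@dataclass(frozen=True)
class SkinToneScale:
    """K ordered tone classes with K−1 descending ITA boundaries.

    A boundary value belongs to the lighter class that lists it as its lower
    bound: the interval of class k is [boundary_k, boundary_{k−1}) read on a
    descending ITA axis, with the outer intervals unbounded.
    """

    name: str
    boundaries: tuple  # K-1 floats, strictly descending
    labels: tuple = field(default=())

    def __post_init__(self):
        b = np.asarray(self.boundaries, dtype=np.float64)
        if b.size < 1:
            raise ValueError("scale needs at least one boundary")
        if not np.all(np.diff(b) < 0):
            raise ValueError("boundaries must be strictly descending")
        if self.labels and len(self.labels) != b.size + 1:
            raise ValueError("labels must number one more than boundaries")
        if not self.labels:
            object.__setattr__(self, "labels", tuple(range(1, b.size + 2)))

    @property
    def n_classes(self) -> int:
        return len(self.boundaries) + 1

    def classify(self, ita) -> ClassAssignment | list[ClassAssignment]:
        """Assign ITA value(s) to tone classes (1 = lightest).

        An ITA exactly equal to a boundary goes to the lighter class, whose
        interval is closed at that lower bound (e.g. Monk ITA 30.61 → tone 5).
        """
        idx = self.classify_index(ita)
        if np.isscalar(ita) or np.asarray(ita).ndim == 0:
            k = int(idx)
            return ClassAssignment(self.name, k, self.labels[k - 1], float(ita))
        return [
            ClassAssignment(self.name, int(k), self.labels[int(k) - 1], float(v))
            for k, v in zip(np.atleast_1d(idx), np.atleast_1d(ita))
        ]

    def classify_index(self, ita) -> np.ndarray | int:
        """Vectorised class index in [1, K]; scalar in, scalar out."""
        arr = np.asarray(ita, dtype=np.float64)
        b = np.asarray(self.boundaries, dtype=np.float64)
        idx = 1 + (b > arr[..., None]).sum(axis=-1)
        return int(idx) if arr.ndim == 0 else idx

    def to_table(self) -> list[dict]:
        """Interval table (class, upper ITA, lower ITA) with ±100 sentinels."""
        hi = [SENTINEL_HI] + list(self.boundaries)
        lo = list(self.boundaries) + [SENTINEL_LO]
        return [
            {"class": k + 1, "label": self.labels[k], "ita_upper": hi[k], "ita_lower": lo[k]}
            for k in range(self.n_classes)
        ]

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps({"name": self.name, "classes": self.to_table()}, indent=2) + "\n"
        )


def derive_thresholds(palette: ReferencePalette) -> SkinToneScale:
    """Calibrate a scale from a reference palette.

    Each swatch's ITA is computed from its Lab color; the threshold between
    adjacent tones is the mean of their ITAs.  Every swatch classifies back
    to its own class under the resulting scale.

    Raises
    ------
    CalibrationError
        If swatch ITAs are not strictly decreasing with tone index; the
        message names the offending adjacent pair.
    """
    itas = palette.itas
    diffs = np.diff(itas)
    if np.any(diffs >= 0):
        i = int(np.argmax(diffs >= 0))
        raise CalibrationError(
            f"palette {palette.name!r}: swatch ITAs not strictly decreasing between "
            f"{palette.labels[i]!r} ({itas[i]:.2f}°) and {palette.labels[i + 1]!r} ({itas[i + 1]:.2f}°)"
        )
    mid = (itas[:-1] + itas[1:]) / 2.0
    return SkinToneScale(name=palette.name, boundaries=tuple(mid), labels=palette.labels)


def monk_scale() -> SkinToneScale:
    """The 10-class Monk scale, recalibrated from the bundled palette."""
    return derive_thresholds(monk_palette())


def fitzpatrick_scale(boundaries=FITZPATRICK_BOUNDARIES) -> SkinToneScale:
    """The 6-class Fitzpatrick phototype scale with published ITA cut-offs."""
    return SkinToneScale(name="fitzpatrick", boundaries=tuple(boundaries), labels=FITZPATRICK_LABELS)
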