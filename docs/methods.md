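# Methods

## Colorimetric model

Skin tone is measured as the Individual Typology Angle (ITA), the angle of
the point (b*, L*) around the pivot L* = 50 in the CIELAB lightness /
blue–yellow plane:

    ITA = arctan((L* − 50) / b*) · 180 / π   [degrees]

ITA runs from +90° (maximally light) to −90° (maximally dark); for real skin
b* is positive and L* typically lies between 20 and 85, so physiological
ITAs fall roughly between −80° and +85°.

**Conventions.** Input pixels are assumed gamma-encoded 8-bit sRGB
(IEC 61966-2-1); conversion to CIELAB uses the D65 illuminant and the 2°
standard observer, the universal defaults for consumer digital images
(`skimage.color` provides the transform). 16-bit inputs must be rescaled to
[0, 255] by the caller. No chromatic adaptation or camera calibration is
attempted.

**Degenerate inputs.** The quotient formula is undefined at b* = 0 and
ambiguous for b* < 0 (non-physiological for skin). We evaluate the
quadrant-aware two-argument arctangent of (L* − 50, b*) and clamp to
[−90°, 90°]: b* = 0 yields ±90° according to the sign of L* − 50, and
negative b* saturates toward ±90° the same way. L* = 50 yields 0° for every
b*, including negative b*, because the numerator vanishes; this keeps the
identity ITA(L*=50, ·) = 0 exact, which the two-argument arctangent alone
would violate in the (measure-zero) quadrant L* = 50, b* < 0. For b* > 0
the result equals the plain formula to machine precision.

**Region aggregation.** The per-image measurement is the arithmetic mean of
per-pixel ITA values over the region (`mean_of_itas`, the default). The
alternative — ITA of the channel-wise mean Lab color (`ita_of_mean_lab`) —
is available behind a flag; the two differ only through the nonlinearity of
the arctangent and agree to well under a degree at realistic noise levels.
We default to the per-pixel mean because it weights every sampled pixel
equally on the angle scale on which classification happens. An empty region
raises, and the pipeline converts that into an exclusion flag rather than a
failure.

## Scales and calibration

A scale is an ordered set of K tone classes (1 = lightest) separated by
K − 1 strictly descending ITA thresholds.

**Monk.** The ten reference swatches published for the Monk Skin Tone Scale
(bundled in `skintone/data/monk_palette.json`, transcribed from the public
source) are converted to Lab and to ITA; the threshold between adjacent
tones is the midpoint of their ITAs. Calibration always recomputes the
thresholds from the palette — the threshold table is never hard-coded — and
a regression test pins the nine derived boundaries (81.60, 75.98, 68.22,
57.51, 30.60, −4.63, −37.76, −66.86, −81.32) to the published correlation
table within 0.05°. Any palette file in the same JSON format can be
calibrated the same way.

**Fitzpatrick.** The six phototypes use the published ITA cut-offs
55, 41, 28, 10, −30 (type I lightest). These bands predate this package and
are config-overridable (`fitzpatrick_config` with a `boundaries` list),
since several variants circulate in the literature.

**Tie-break.** An ITA exactly equal to a threshold is assigned to the
lighter class — each class interval is closed at its lower ITA bound (Monk
tone 5 is [30.60°, 57.51°)). Exact threshold hits are measure-zero in
practice; a consistent documented convention matters more than the choice
itself. Serialized tables retain cosmetic ±100 outer sentinels; the
classifier treats the outer intervals as unbounded.

## Region extraction

The package consumes detector *outputs* — body-part label maps (single
channel integer PNGs, dense-pose IUV part convention) and 68-point facial
landmark files (long CSV `index,x,y[,confidence]` or the OpenFace wide
dialect) — and never runs neural inference itself, so any segmentation or
landmark backend can feed it.

- Arm pixels: all and only pixels labeled 19 or 20 (left/right lower arm),
  in row-major order, with per-label counts in the sample provenance.
- Face pixels: the nasal-bridge landmarks 27–30 rounded half-up to pixel
  coordinates (0-based, x right, y down). Default radius 0 samples exactly
  four pixels; radius r takes the union of (2r+1)² neighborhoods, clipped
  and deduplicated. Any nasal landmark out of frame empties the sample with
  the reason recorded.
- Arm regions with fewer than `min_arm_pixels` (default 50) matching pixels
  are excluded as unreliable; the threshold is a package choice, set well
  below any plausible genuine forearm detection at typical resolutions but
  high enough to reject stray mislabeled pixels.

Unusable regions are always flagged (`no_region`, `below_min_pixels`,
`landmarks_out_of_frame`, `human_excluded`) and never silently dropped; a
batch run emits one row per image and region regardless. Judgments that
require clinical context — erythema, tattoos — are accepted as a per-image
exclusion list rather than detected automatically.

## Evaluation metrics

Gold and predicted classes are compared with a deviation margin interpreted
as a fraction of the scale: correct ⇔ |pred − gold| ≤ floor(margin · K).
With the default 10% margin this is a one-class tolerance on the 10-class
Monk scale and exact match on the 6-class Fitzpatrick scale; the 20%
"sufficient accuracy" margin is two Monk classes or one Fitzpatrick class.
This class-fraction reading is the default because it makes the two scales'
margins commensurate (20% ≈ one Fitzpatrick class shift); an alternative
reading of the margin as a fraction of the 200° span of the serialized ITA
table (`margin_semantics="ita_fraction"`) is implemented for sensitivity
analyses. Accuracy is monotonically non-decreasing in the margin, so
accuracy ≤ sufficient accuracy always.

Balanced accuracy is the unweighted mean of per-class recalls under the same
margin, averaged only over classes with gold support (a recall of an absent
class is undefined, not zero). Fleiss' kappa is computed in the standard
form (observed vs chance agreement from the category prevalences) and is
cross-checked against statsmodels in the test suite. The Mann–Whitney U test
uses exact enumeration when both groups have n ≤ 8 without ties, otherwise
the tie-corrected normal approximation with continuity correction (via
scipy); subgroup comparisons (arm vs face, image types, lighter vs darker
half of the scale) compare per-image correctness indicators by default, with
absolute class deviation as the alternative variable. No multiple-testing
correction is applied; p-values are reported raw.

## Synthetic cohorts

The generator emulates a standardized validation cohort: one person per
image, flat lighting, known skin color. Each record paints two arm
rectangles (labeled 19/20) and a face block (landmarks 27–30 on its
midline) in a color drawn from a Monk reference swatch — so the gold class,
gold Lab and gold ITA are exact by construction — plus isotropic Gaussian
noise in Lab (perceptually more uniform than RGB noise; default σ = 2 Lab
units, a mild sensor/texture level). Options: a multiplicative L* ramp to
mimic uneven illumination, class weights to reproduce imbalance toward
intermediate tones, and an arm-less fraction (exactly round(f·n) records,
chosen at random) to exercise the exclusion path. Everything is reproducible
from (spec, seed).

What passing synthetic tests shows — and does not. The cohort validates the
measurement chain: extraction fidelity, colorimetric correctness,
calibration, classification and scoring. It does not contain skin texture,
erythema, hair, makeup, pose variation, or detector segmentation errors, so
synthetic accuracies are upper bounds that say nothing about detector
quality or clinical image variability.

## Problem sizes and numerical choices

The acceptance run (`scripts/acceptance.py`) uses a 100-image noiseless
cohort (round-trip check) and a 120-image cohort at the default σ = 2 with
5% arm-less records, at 160×120 px — sizes chosen so the full run completes
in seconds while every tone class is still sampled. Lab noise at the
default σ leaves the per-region mean ITA within a fraction of a degree of
truth (≈2000 arm pixels per image), so Monk misclassifications appear only
from σ ≈ 5 upward; the four-pixel nasal sample is the noise-sensitive path.
8-bit quantization of painted colors perturbs ITA by under 0.5°, which the
tests allow for explicitly.

## Known limitations

- ITA reduces skin tone to two Lab coordinates; it does not model texture,
  pigmentation irregularities or erythema, and lighting shifts translate
  directly into ITA shifts.
- Fitzpatrick ITA bands are a repurposing of a UV-response phototype;
  agreement of ITA-based Fitzpatrick assignments with clinician ratings is
  known to be poor, and this package ships them only for comparability.
- One person per image is assumed; overlapping detections are out of scope.
- The Monk thresholds inherit any colorimetric error in the published
  swatches; recalibrate from a different palette file if a revised reference
  is published.
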