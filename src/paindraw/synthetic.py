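"""Seeded synthetic cohorts of pain drawings.

The study cohort (60 Ehlers-Danlos syndrome patients, 32 Guillain-Barré
syndrome patients) is not publicly deposited, so this module generates
stand-in cohorts: each subject's binary pain mask is sampled by including
each named anatomical region independently with a disease-specific
probability, and the mask is then rendered onto the printed sheet as a
distorted "scan" (global shift + rotation, salt-pepper speckle) for
end-to-end testing of the calibration and preprocessing stages.

Default regional marking probabilities are the midpoints of the frequency
bands reported for the two diseases: for EDS, spine/tailbone/knees at 70%
(band 60-80%), shoulders/elbows/thumb saddle at 45% (40-50%), and a set of
further joints at 35% (30-40%); for GBS, dorsal and plantar feet at 65%
(60-70%), palmar fingertips and tailbone at 45% (40-50%), left dorsal palm
at 30%, and right dorsal palm / thumb saddle at 25% ("up to 30%").
Regions a disease's table does not list have probability 0.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.morphology import dilation as _dilation
from skimage.morphology import disk
from skimage.morphology import erosion as _erosion
from skimage.transform import SimilarityTransform, warp

from .template import REGION_NAMES, TemplateSpec, region_mask, render_blank_sheet

__all__ = [
    "RegionProbabilityTable",
    "NoiseModel",
    "SyntheticDrawing",
    "SyntheticCohort",
    "default_probability_tables",
    "sample_pain_mask",
    "render_scanned_sheet",
    "generate_cohort",
]

EDS_LABEL = "EDS"
GBS_LABEL = "GBS"


@dataclass(frozen=True)
class RegionProbabilityTable:
    """Per-region Bernoulli marking probabilities for one disease."""

    disease_label: str
    probs: dict[str, float]

    def __post_init__(self):
        for name, p in self.probs.items():
            if name not in REGION_NAMES:
                raise ValueError(f"unknown region name: {name!r}")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability for {name!r} out of [0,1]: {p}")

    def probability(self, region: str) -> float:
        if region not in REGION_NAMES:
            raise ValueError(f"unknown region name: {region!r}")
        return self.probs.get(region, 0.0)


@dataclass(frozen=True)
class NoiseModel:
    """Scanning-artifact model: rigid misalignment plus pixel speckle.

    shift_range     max |dx|, |dy| in pixels (uniform draw)
    rotation_range  max |theta| in degrees (uniform draw, about canvas center)
    speckle_density fraction of pixels flipped to black
    stroke_jitter   amplitude (px) of random per-drawing boundary
                    dilation/erosion of the marked areas
    """

    shift_range: float = 10.0
    rotation_range: float = 3.0
    speckle_density: float = 0.0005
    stroke_jitter: int = 1

    def __post_init__(self):
        if min(self.shift_range, self.rotation_range,
               self.speckle_density, self.stroke_jitter) < 0:
            raise ValueError("noise parameters must be non-negative")
        if self.rotation_range >= 15.0:
            raise ValueError("rotation_range must be below 15 degrees")

    @classmethod
    def none(cls) -> "NoiseModel":
        return cls(0.0, 0.0, 0.0, 0)


@dataclass(frozen=True)
class SyntheticDrawing:
    """One synthetic subject: ground truth plus its rendered scan."""

    id: str
    disease_label: str
    mask: np.ndarray          # bool, canvas-sized ground truth
    scan: np.ndarray          # uint8 grayscale rendered scan
    transform: tuple[float, float, float]  # true (dx, dy, theta_deg)
    empty: bool = False       # flagged when no region was sampled


@dataclass(frozen=True)
class SyntheticCohort:
    drawings: tuple[SyntheticDrawing, ...]
    seed: int
    spec: TemplateSpec = field(repr=False)

    def write(self, outdir) -> Path:
        """Write scans, truth masks and a manifest CSV; return manifest path."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest = outdir / "manifest.csv"
        with open(manifest, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(
                ["id", "label", "scan_path", "mask_path", "dx", "dy", "theta_deg"]
            )
            for d in self.drawings:
                scan_path = outdir / f"{d.id}_scan.png"
                mask_path = outdir / f"{d.id}_mask.png"
                Image.fromarray(d.scan).save(scan_path)
                Image.fromarray((d.mask * np.uint8(255))).save(mask_path)
                writer.writerow(
                    [d.id, d.disease_label, scan_path.name, mask_path.name,
                     f"{d.transform[0]:.4f}", f"{d.transform[1]:.4f}",
                     f"{d.transform[2]:.4f}"]
                )
        return manifest


def default_probability_tables() -> tuple[RegionProbabilityTable, RegionProbabilityTable]:
    """Default (EDS, GBS) tables: midpoints of the reported frequency bands."""
    eds = RegionProbabilityTable(
        EDS_LABEL,
        {
            "spine_with_neck": 0.70,
            "tailbone": 0.70,
            "knee_front": 0.70,
            "shoulder": 0.45,
            "elbow": 0.45,
            "thumb_saddle_joint": 0.45,
            "umbilical": 0.35,
            "groin": 0.35,
            "knee_back": 0.35,
            "ankle": 0.35,
            "hand_finger_joints": 0.35,
            "metatarsophalangeal": 0.35,
            "heel": 0.35,
        },
    )
    gbs = RegionProbabilityTable(
        GBS_LABEL,
        {
            "foot_dorsal": 0.65,
            "foot_plantar": 0.65,
            "fingertips_palmar": 0.45,
            "tailbone": 0.45,
            "palm_dorsal_left": 0.30,
            "palm_dorsal_right": 0.25,
            "thumb_saddle_joint": 0.25,
        },
    )
    return eds, gbs


def sample_pain_mask(
    spec: TemplateSpec,
    table: RegionProbabilityTable,
    rng: np.random.Generator,
    stroke_jitter: int = 0,
) -> tuple[np.ndarray, bool]:
    """Draw one subject's binary mask; returns (mask, is_empty).

    Each region is included independently with its table probability; the
    mask is the union of included region masks, optionally eroded/dilated
    by a random amplitude up to ``stroke_jitter`` pixels to emulate pen
    stroke variability.  Regions with probability 0 never appear.
    """
    mask = np.zeros(spec.shape, dtype=bool)
    draws = rng.random(len(REGION_NAMES))
    for name, u in zip(REGION_NAMES, draws):
        if u < table.probability(name):
            mask |= region_mask(spec, name)
    if stroke_jitter > 0 and mask.any():
        amp = int(rng.integers(-stroke_jitter, stroke_jitter + 1))
        if amp > 0:
            mask = _dilation(mask, disk(amp))
        elif amp < 0:
            mask = _erosion(mask, disk(-amp))
    return mask, not mask.any()


def render_scanned_sheet(
    spec: TemplateSpec,
    mask: np.ndarray,
    noise: NoiseModel,
    rng: np.random.Generator,
    blank: np.ndarray | None = None,
    transform: tuple[float, float, float] | None = None,
) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Composite a mask onto the printed sheet and distort it like a scan.

    The sheet with the blackened mask is rotated by theta about the canvas
    center and shifted by (dx, dy) (amounts drawn uniformly within the
    noise ranges, or taken verbatim from ``transform`` when given), then
    speckled.  Returns the uint8 scan and the true (dx, dy, theta_deg),
    where dx is a column offset and dy a row offset.
    """
    if mask.shape != spec.shape:
        raise ValueError("mask dimensions must equal the template canvas")
    if blank is None:
        blank = render_blank_sheet(spec)
    page = blank.copy()
    page[mask] = 0

    if transform is not None:
        dx, dy, theta = (float(v) for v in transform)
    else:
        dx = float(rng.uniform(-noise.shift_range, noise.shift_range))
        dy = float(rng.uniform(-noise.shift_range, noise.shift_range))
        theta = float(rng.uniform(-noise.rotation_range, noise.rotation_range))

    if dx or dy or theta:
        scan = _apply_rigid(page, dx, dy, theta)
    else:
        scan = page

    if noise.speckle_density > 0:
        flips = rng.random(scan.shape) < noise.speckle_density
        scan = scan.copy()
        scan[flips] = 0
    return scan, (dx, dy, theta)


def _apply_rigid(img: np.ndarray, dx: float, dy: float, theta_deg: float) -> np.ndarray:
    """Rotate about the canvas center then translate; white background."""
    h, w = img.shape
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])  # (x, y)
    t = (
        SimilarityTransform(translation=-center)
        + SimilarityTransform(rotation=np.deg2rad(theta_deg))
        + SimilarityTransform(translation=center + np.array([dx, dy]))
    )
    out = warp(img.astype(float) / 255.0, t.inverse, order=1, cval=1.0,
               preserve_range=True)
    return np.clip(np.rint(out * 255.0), 0, 255).astype(np.uint8)


def generate_cohort(
    n_a: int,
    n_b: int,
    seed: int,
    noise: NoiseModel | None = None,
    spec: TemplateSpec | None = None,
    tables: tuple[RegionProbabilityTable, RegionProbabilityTable] | None = None,
) -> SyntheticCohort:
    """Generate ``n_a`` disease-A and ``n_b`` disease-B drawings, seeded.

    Fully reproducible: the same seed yields bit-identical cohorts.
    """
    if n_a < 1 or n_b < 1:
        raise ValueError("cohort sizes must be at least 1")
    if noise is None:
        noise = NoiseModel()
    if spec is None:
        from .template import build_default_template

        spec = build_default_template()
    if tables is None:
        tables = default_probability_tables()
    rng = np.random.default_rng(seed)
    blank = render_blank_sheet(spec)
    drawings = []
    for table, n in zip(tables, (n_a, n_b)):
        for i in range(n):
            mask, empty = sample_pain_mask(
                spec, table, rng, stroke_jitter=noise.stroke_jitter
            )
            scan, transform = render_scanned_sheet(spec, mask, noise, rng, blank=blank)
            drawings.append(
                SyntheticDrawing(
                    id=f"{table.disease_label.lower()}_{i + 1:03d}",
                    disease_label=table.disease_label,
                    mask=mask,
                    scan=scan,
                    transform=transform,
                    empty=empty,
                )
            )
    return SyntheticCohort(drawings=tuple(drawings), seed=seed, spec=spec)
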