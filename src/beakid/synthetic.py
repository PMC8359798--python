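"""Synthetic cephalopod-beak image generator.

Real study material consists of left-lateral photographs of upper and lower
beaks lying on a white lightbox: a single dark, hook-shaped chitinous
silhouette on a near-white background.  This module emulates exactly that
statistical structure — species-specific silhouette shape, a pigmentation
gradient that darkens toward the rostrum, bright background (grey levels
within 240–255) — so that every downstream stage (threshold segmentation,
HOG, shape descriptors, classification) can be exercised end to end with a
known ground truth and no external data.

The silhouette is a closed hooked-crescent polygon built from cubic Bézier
arcs: a dorsal hood dome running from the tail join to the rostrum tip, a
short hooked rostrum arc, a concave notch, and a ventral wing lobe.  Species
are told apart by the hood-to-wing proportion, wing length, hook curvature
and pigmentation parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.draw import polygon as draw_polygon

from .errors import InvalidParameterError, InvalidViewError

VIEWS = ("upper", "lower")

#: Nominal lightbox field of view covered by the image width, in mm.
FIELD_OF_VIEW_MM = 160.0


@dataclass(frozen=True)
class SpeciesShapeParams:
    """Shape and pigmentation parameters of one species' beak silhouette.

    Parameters
    ----------
    species_id:
        Species label written to the manifest.
    rostrum_curvature:
        Dimensionless > 0; scales how far the hooked rostrum tip bends
        ventrally.
    hood_to_wing_ratio:
        Dimensionless > 0; ratio of the dorsal hood height to the ventral
        wing depth.  The main determinant of the silhouette aspect ratio.
    wing_length_frac:
        Fraction of the body length (0, 1] spanned by the ventral wing lobe.
    base_darkness:
        Grey level (0–255) of the beak at the rostrum tip; must stay below
        200 so the object is always darker than the lightbox background.
    darkness_gradient:
        Grey-level increase per unit of normalised distance from the rostrum
        (the rostrum is the most heavily pigmented, hence darkest, region).
    size_mm_range:
        (min, max) nominal beak length in millimetres; each generated sample
        draws its length uniformly from this range.
    tint_rgb:
        Per-channel multipliers applied to the pigmentation grey level.
        Chitin hue varies with the species' darkening stage, so the channel
        ratios are species-specific: colour descriptors see structure that a
        single grey channel does not.
    """

    species_id: str
    rostrum_curvature: float
    hood_to_wing_ratio: float
    wing_length_frac: float
    base_darkness: float
    darkness_gradient: float
    size_mm_range: tuple[float, float]
    tint_rgb: tuple[float, float, float] = (1.12, 0.92, 0.72)

    def validate(self) -> None:
        numeric = {
            "rostrum_curvature": self.rostrum_curvature,
            "hood_to_wing_ratio": self.hood_to_wing_ratio,
            "wing_length_frac": self.wing_length_frac,
            "base_darkness": self.base_darkness,
            "darkness_gradient": self.darkness_gradient,
        }
        for name, value in numeric.items():
            if not math.isfinite(value):
                raise InvalidParameterError(f"{name} must be finite, got {value!r}")
        if self.rostrum_curvature <= 0 or self.hood_to_wing_ratio <= 0:
            raise InvalidParameterError("shape parameters must be positive")
        if not 0 < self.wing_length_frac <= 1:
            raise InvalidParameterError(
                f"wing_length_frac must lie in (0, 1], got {self.wing_length_frac}"
            )
        if not 0 <= self.base_darkness < 200:
            raise InvalidParameterError(
                f"base_darkness must lie in [0, 200), got {self.base_darkness}"
            )
        lo, hi = self.size_mm_range
        if not (math.isfinite(lo) and math.isfinite(hi) and 0 < lo < hi):
            raise InvalidParameterError(f"invalid size_mm_range {self.size_mm_range}")


# Seven study species: four squids, two cuttlefish, one octopus.  The shape
# parameters are stylised, chosen so that every pair of species differs in
# hood_to_wing_ratio by at least 20% — comfortably separable silhouettes,
# the regime the identification pipeline assumes.
SPECIES_TABLE: dict[str, SpeciesShapeParams] = {
    p.species_id: p
    for p in (
        SpeciesShapeParams("Loliolus uyii", 0.9, 0.60, 0.60, 60.0, 110.0, (18.0, 30.0), (1.18, 0.92, 0.62)),
        SpeciesShapeParams("Uroteuthis chinensis", 1.1, 0.76, 0.70, 80.0, 90.0, (30.0, 48.0), (1.10, 0.95, 0.72)),
        SpeciesShapeParams("Uroteuthis edulis", 1.3, 0.95, 0.78, 95.0, 75.0, (28.0, 45.0), (1.06, 0.88, 0.78)),
        SpeciesShapeParams("Sepioteuthis lessoniana", 1.0, 1.18, 0.66, 50.0, 120.0, (35.0, 55.0), (1.22, 0.86, 0.60)),
        SpeciesShapeParams("Sepia aculeata", 1.4, 1.48, 0.84, 40.0, 60.0, (32.0, 50.0), (1.02, 0.94, 0.82)),
        SpeciesShapeParams("Sepia esculenta", 1.2, 1.85, 0.74, 70.0, 95.0, (30.0, 46.0), (1.15, 0.82, 0.68)),
        SpeciesShapeParams("Amphioctopus aegina", 0.8, 2.30, 0.88, 55.0, 50.0, (16.0, 26.0), (1.00, 1.00, 0.88)),
    )
}

#: Taxon totals from the study cohort: 96 squids over four species, 49
#: cuttlefish over two, 29 octopus.  Per-species numbers are split evenly
#: within each taxon (the odd cuttlefish sample goes to Sepia aculeata).
DEFAULT_COUNTS: dict[str, int] = {
    "Loliolus uyii": 24,
    "Uroteuthis chinensis": 24,
    "Uroteuthis edulis": 24,
    "Sepioteuthis lessoniana": 24,
    "Sepia aculeata": 25,
    "Sepia esculenta": 24,
    "Amphioctopus aegina": 29,
}


@dataclass(frozen=True)
class SyntheticDatasetConfig:
    """Configuration of one synthetic beak dataset.

    ``image_size_px`` is (width, height); the default matches the native
    resolution of the study's smartphone photographs.  The background grey
    range must stay within [240, 255] so that threshold-240 segmentation
    separates beak from lightbox exactly.
    """

    per_species_counts: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_COUNTS))
    image_size_px: tuple[int, int] = (5312, 2988)
    background_level_range: tuple[float, float] = (244.0, 252.0)
    noise_sd: float = 3.0
    jpeg_quality: int | None = None
    view: str = "lower"
    seed: int = 0

    def validate(self) -> None:
        if not self.per_species_counts:
            raise InvalidParameterError("per_species_counts must name at least one species")
        for label, count in self.per_species_counts.items():
            if count < 1:
                raise InvalidParameterError(f"count for {label!r} must be >= 1, got {count}")
            if label not in SPECIES_TABLE:
                raise InvalidParameterError(f"unknown species label {label!r}")
        lo, hi = self.background_level_range
        if not (240.0 <= lo <= hi <= 255.0):
            raise InvalidParameterError(
                f"background range must be a subset of [240, 255], got {self.background_level_range}"
            )
        if self.view not in VIEWS:
            raise InvalidViewError(f"view must be one of {VIEWS}, got {self.view!r}")
        w, h = self.image_size_px
        if w < 32 or h < 32:
            raise InvalidParameterError("image size too small to hold a beak silhouette")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")
        if self.jpeg_quality is not None and not 1 <= self.jpeg_quality <= 100:
            raise InvalidParameterError("jpeg_quality must lie in [1, 100] or be None")


def default_study_config(seed: int = 0, **overrides) -> SyntheticDatasetConfig:
    """Dataset configuration mirroring the study cohort.

    Seven species, 174 samples: 96 squids (24 per species), 49 cuttlefish
    (25 + 24) and 29 octopus.
    """
    cfg = SyntheticDatasetConfig(seed=seed, **overrides)
    cfg.validate()
    return cfg


def _cubic_bezier(p0, p1, p2, p3, n: int) -> np.ndarray:
    """Sample a cubic Bézier arc, endpoint excluded (arcs are chained)."""
    t = np.linspace(0.0, 1.0, n, endpoint=False)[:, None]
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    return (
        (1 - t) ** 3 * p0
        + 3 * (1 - t) ** 2 * t * p1
        + 3 * (1 - t) * t**2 * p2
        + t**3 * p3
    )


def beak_outline(params: SpeciesShapeParams, view: str) -> np.ndarray:
    """Closed beak silhouette polygon in normalised units.

    Coordinates: x in [0, 1] runs tail → rostrum tip, y grows ventrally
    (downward in image coordinates for the lower beak).  The upper beak is
    the dorsoventral mirror of the same construction.
    """
    if view not in VIEWS:
        raise InvalidViewError(f"view must be one of {VIEWS}, got {view!r}")
    params.validate()

    wing_depth = 0.30
    hood_height = wing_depth * params.hood_to_wing_ratio
    rc = params.rostrum_curvature
    x_wing = 1.0 - params.wing_length_frac  # wing lobe low point

    tail = (0.0, -0.2 * hood_height)
    tip = (1.0, 0.0)
    hook = (0.90, 0.12 * rc)
    wing_low = (x_wing, wing_depth)

    pts = np.vstack(
        [
            # dorsal hood dome: tail join -> rostrum tip
            _cubic_bezier(tail, (0.25, -hood_height), (0.70, -0.95 * hood_height), tip, 120),
            # hooked rostrum: tip bends ventrally and back
            _cubic_bezier(tip, (1.0 + 0.05 * rc, 0.05 * rc), (0.97, 0.10 * rc), hook, 40),
            # concave crescent notch into the ventral wing lobe
            _cubic_bezier(hook, (0.75, 0.05), (0.60, 0.10), wing_low, 80),
            # wing lobe back to the tail join
            _cubic_bezier(wing_low, (0.5 * x_wing, 0.9 * wing_depth), (0.03, 0.3 * wing_depth), tail, 80),
        ]
    )
    if view == "upper":
        pts = pts * np.array([1.0, -1.0])
    return pts


def generate_beak_image(
    params: SpeciesShapeParams,
    view: str,
    rng_seed: int,
    *,
    image_size_px: tuple[int, int] = (5312, 2988),
    background_level_range: tuple[float, float] = (244.0, 252.0),
    noise_sd: float = 3.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Render one synthetic beak photograph and its ground-truth mask.

    Returns
    -------
    image : (H, W, 3) uint8
        RGB image: one dark hooked-crescent silhouette on a bright lightbox
        background.  All background channel values lie within the configured
        240–255 range; all object channel values stay below 240, so the
        grey-level threshold at 240 recovers the mask exactly.
    mask : (H, W) bool
        True exactly on silhouette pixels.
    """
    if view not in VIEWS:
        raise InvalidViewError(f"view must be one of {VIEWS}, got {view!r}")
    params.validate()
    lo, hi = background_level_range
    if not (240.0 <= lo <= hi <= 255.0):
        raise InvalidParameterError("background range must be a subset of [240, 255]")

    width, height = image_size_px
    rng = np.random.default_rng(rng_seed)

    outline = beak_outline(params, view)

    # Sample a nominal size, convert to pixels through the fixed lightbox
    # field of view, and place the beak near the frame centre with a small
    # random offset and rotation (photographs are hand-placed, not aligned).
    length_mm = rng.uniform(*params.size_mm_range)
    px_per_mm = width / FIELD_OF_VIEW_MM
    length_px = length_mm * px_per_mm
    angle = math.radians(rng.normal(0.0, 2.0))
    cos_a, sin_a = math.cos(angle), math.sin(angle)
    rot = np.array([[cos_a, -sin_a], [sin_a, cos_a]])
    centred = (outline - outline.mean(axis=0)) * length_px
    pts = centred @ rot.T
    centre = np.array([width / 2, height / 2]) + rng.uniform(-0.03, 0.03, size=2) * min(width, height)
    pts = pts + centre

    rr, cc = draw_polygon(pts[:, 1], pts[:, 0], shape=(height, width))
    mask = np.zeros((height, width), dtype=bool)
    mask[rr, cc] = True

    # Lightbox background: per-image base level plus sensor noise, clipped so
    # every channel stays within [240, 255].
    base = rng.uniform(lo, hi)
    img = np.empty((height, width, 3), dtype=np.float32)
    img[:] = base
    if noise_sd > 0:
        img += noise_sd * rng.standard_normal(img.shape, dtype=np.float32)
    np.clip(img, lo, hi, out=img)

    # Beak pigmentation: darkest at the rostrum tip, fading with normalised
    # distance from it; a warm chitin tint separates the RGB channels.
    tip_xy = (np.array([1.0, 0.0]) - outline.mean(axis=0)) * length_px @ rot.T + centre
    dist = np.hypot(cc - tip_xy[0], rr - tip_xy[1]) / length_px
    grey = params.base_darkness + params.darkness_gradient * dist
    if noise_sd > 0:
        grey = grey + noise_sd * rng.standard_normal(grey.shape)
    for ch, tint in enumerate(params.tint_rgb):
        img[rr, cc, ch] = np.clip(grey * tint, 5.0, 235.0)

    return np.rint(img).astype(np.uint8), mask


def _image_seed(config_seed: int, species_index: int, sample_index: int) -> int:
    ss = np.random.SeedSequence([config_seed, species_index, sample_index])
    return int(ss.generate_state(1)[0])


def _safe_name(label: str) -> str:
    return label.lower().replace(" ", "_")


def generate_dataset(config: SyntheticDatasetConfig, out_dir: str | Path) -> pd.DataFrame:
    """Write a full labelled dataset and its manifest CSV.

    One image (and ground-truth mask PNG) per record; the manifest
    ``manifest.csv`` has columns ``path,label,view,mask_path`` with paths
    relative to ``out_dir``.  Identical config (including seed) yields a
    byte-identical dataset.
    """
    config.validate()
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)

    records = []
    for sp_idx, label in enumerate(sorted(config.per_species_counts)):
        params = SPECIES_TABLE[label]
        for i in range(config.per_species_counts[label]):
            seed = _image_seed(config.seed, sp_idx, i)
            img, mask = generate_beak_image(
                params,
                config.view,
                seed,
                image_size_px=config.image_size_px,
                background_level_range=config.background_level_range,
                noise_sd=config.noise_sd,
            )
            stem = f"{_safe_name(label)}_{config.view}_{i:03d}"
            if config.jpeg_quality is None:
                img_rel = f"images/{stem}.png"
                Image.fromarray(img).save(out_dir / img_rel)
            else:
                img_rel = f"images/{stem}.jpg"
                Image.fromarray(img).save(out_dir / img_rel, quality=config.jpeg_quality)
            mask_rel = f"masks/{stem}.png"
            Image.fromarray(mask.astype(np.uint8) * 255).save(out_dir / mask_rel)
            records.append(
                {"path": img_rel, "label": label, "view": config.view, "mask_path": mask_rel}
            )

    manifest = pd.DataFrame.from_records(records, columns=["path", "label", "view", "mask_path"])
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def load_manifest(path: str | Path) -> pd.DataFrame:
    """Read a manifest CSV (columns ``path,label,view[,mask_path]``)."""
    manifest = pd.read_csv(path)
    missing = {"path", "label", "view"} - set(manifest.columns)
    if missing:
        raise InvalidParameterError(f"manifest is missing columns {sorted(missing)}")
    return manifest
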