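"""Leaf morphology and wood traits measured off the sampled branch.

Leaf area comes from flatbed scans (binary images at a known dpi),
specific leaf area (SLA) from pooled leaf area over pooled dry mass,
and wood density from branch dry mass over water-displacement volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MM_PER_INCH = 25.4


class EmptyScanError(ValueError):
    """A leaf scan contained no foreground pixels."""


@dataclass
class LeafScan:
    """A thresholded leaf scan: True/1 pixels are leaf."""

    image: np.ndarray
    dpi: float
    tree_id: str = ""

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image).astype(bool)
        if self.dpi <= 0:
            raise ValueError("dpi must be positive")


@dataclass
class WoodSample:
    """Branch segment dry mass (g) and displacement volume (cm^3)."""

    dry_mass_g: float
    volume_cm3: float
    tree_id: str = ""

    def __post_init__(self) -> None:
        if self.dry_mass_g <= 0 or self.volume_cm3 <= 0:
            raise ValueError("dry mass and volume must be positive")


def read_leaf_scan(path, dpi: float, tree_id: str = "",
                   threshold: str = "otsu") -> LeafScan:
    """Load a PNG/TIFF leaf scan and binarize it.

    Already-binary images (two distinct values) are taken as-is with
    the darker value as leaf; greyscale/RGB images are collapsed to
    grey and thresholded with Otsu's method.
    """
    import imageio.v3 as iio

    img = np.asarray(iio.imread(path), dtype=float)
    if img.ndim == 3:
        img = img[..., :3].mean(axis=2)
    levels = np.unique(img)
    if len(levels) <= 2:
        return LeafScan(img == levels[0], dpi=dpi, tree_id=tree_id)
    if threshold != "otsu":
        raise ValueError(f"unknown threshold method {threshold!r}")
    return binarize_scan(img, dpi=dpi, tree_id=tree_id)


def binarize_scan(gray: np.ndarray, dpi: float, tree_id: str = "") -> LeafScan:
    """Threshold a greyscale scan with Otsu's method (dark leaf on a
    light scanner background)."""
    from skimage.filters import threshold_otsu

    gray = np.asarray(gray, dtype=float)
    thresh = threshold_otsu(gray)
    return LeafScan(gray < thresh, dpi=dpi, tree_id=tree_id)


def leaf_area_from_scan(scan: LeafScan) -> float:
    """Leaf area in cm^2: foreground pixels times the physical pixel
    area (25.4/dpi mm on each side)."""
    n_fg = int(scan.image.sum())
    if n_fg == 0:
        raise EmptyScanError("no foreground pixels in scan")
    pixel_mm = MM_PER_INCH / scan.dpi
    area_mm2 = n_fg * pixel_mm ** 2
    return area_mm2 / 100.0


def sla(total_area_mm2: float, dry_mass_mg: float) -> float:
    """Specific leaf area (mm^2/mg) from pooled area and pooled mass.

    For multi-leaf samples the areas and masses are summed before the
    division (one pooled ratio, not a mean of per-leaf ratios).
    """
    if total_area_mm2 <= 0 or dry_mass_mg <= 0:
        raise ValueError("area and mass must be positive")
    return total_area_mm2 / dry_mass_mg


def sla_pooled(areas_mm2, masses_mg) -> float:
    """Pool leaves (sum areas, sum masses) then take the ratio."""
    areas = np.asarray(areas_mm2, dtype=float)
    masses = np.asarray(masses_mg, dtype=float)
    if areas.shape != masses.shape:
        raise ValueError("need one mass per leaf")
    return sla(float(areas.sum()), float(masses.sum()))


def wood_density(sample: WoodSample) -> float:
    """Branch wood density in g/cm^3 (dry mass / displacement volume)."""
    return sample.dry_mass_g / sample.volume_cm3
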