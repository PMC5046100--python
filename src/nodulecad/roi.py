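"""Core data model for candidate-nodule regions of interest.

A candidate ROI is a small volumetric crop of a CT scan together with a
co-registered binary segmentation mask.  Arrays are indexed ``(z, y, x)``,
0-based; any nonzero mask value is foreground.  All feature formulas operate
in voxel units (the mask is a set of lattice points); physical spacing is
carried along for provenance and optional millimetre scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

#: Fixed 42-slot feature schema.  Shape block fs1..fs18, intensity block
#: fi1..fi8, texture block ft1..ft16.  The order is identical everywhere in
#: the package (extraction, CSV files, decision tables, classifiers).
SHAPE_NAMES = tuple(f"fs{i}" for i in range(1, 19))
INTENSITY_NAMES = tuple(f"fi{i}" for i in range(1, 9))
TEXTURE_NAMES = tuple(f"ft{i}" for i in range(1, 17))
FEATURE_NAMES: Tuple[str, ...] = SHAPE_NAMES + INTENSITY_NAMES + TEXTURE_NAMES

#: Human-readable meaning of every slot.
FEATURE_DESCRIPTIONS = {
    "fs1": "perimeter of representative slice (boundary pixel count)",
    "fs2": "area of representative slice (foreground pixel count)",
    "fs3": "volume (foreground voxel count)",
    "fs4": "circularity C^2 / (4*pi*S)",
    "fs5": "rectangularity S / (H*W)",
    "fs6": "elongation min(H,W) / max(H,W)",
    "fs7": "Euler number (components - holes)",
    "fs8": "ESV: volume over circumscribed-sphere volume",
    "fs9": "SCDSTD: CV of surface-to-centroid distances",
    "fs10": "ERCLD: normalized centroid-to-box-edge-midpoint distance",
    "fs11": "maximum 3D diameter (Feret, voxel units)",
    **{f"fs{11 + k}": f"Hu moment invariant C{k} (log10-compressed)" for k in range(1, 8)},
    "fi1": "mean intensity",
    "fi2": "intensity variance (population)",
    "fi3": "max-min intensity difference",
    "fi4": "intensity skewness",
    "fi5": "intensity kurtosis (Pearson)",
    "fi6": "intensity gradient inside-to-outside (erosion-shell ratio score)",
    "fi7": "Laplace divergence mean (LDM)",
    "fi8": "Laplace divergence distance (LDD)",
    "ft1": "Tamura contrast",
    "ft2": "Tamura directionality",
    "ft3": "Tamura coarseness",
    "ft4": "GLCM angular second moment",
    "ft5": "GLCM contrast (moment of inertia)",
    "ft6": "GLCM inverse difference moment",
    "ft7": "GLCM sum average",
    "ft8": "GLCM variance",
    "ft9": "GLCM sum variance",
    "ft10": "GLCM difference variance",
    "ft11": "GLCM entropy",
    "ft12": "GLCM sum entropy",
    "ft13": "GLCM difference entropy",
    "ft14": "GLCM information measure of correlation 1",
    "ft15": "GLCM correlation coefficient",
    "ft16": "GLCM maximal correlation coefficient",
}

#: Morphology tags.  Nodule morphologies: solitary (SPN), vascular-adhesion
#: (VAPN), pleural-adhesion (PAPN).
NODULE_LABELS = frozenset({"SPN", "VAPN", "PAPN"})


@dataclass
class RoiVolume:
    """A segmented 3D candidate region: intensities + binary mask + spacing.

    Parameters
    ----------
    intensities : (Z, Y, X) float array of image gray values.
    mask : array of the same shape; nonzero marks foreground.
    spacing : per-axis voxel size in mm, (z, y, x) order.
    label : "SPN" | "VAPN" | "PAPN" | "non-nodule" | "unknown".
    id : identifier string used in feature tables and manifests.
    """

    intensities: np.ndarray
    mask: np.ndarray
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    label: str = "unknown"
    id: str = "roi"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        mask = np.asarray(self.mask)
        if mask.shape != self.intensities.shape:
            raise ValueError(
                f"mask shape {mask.shape} does not match image shape "
                f"{self.intensities.shape}"
            )
        if self.intensities.ndim != 3:
            raise ValueError("RoiVolume expects 3D arrays (z, y, x)")
        self.mask = mask != 0
        if not self.mask.any():
            raise ValueError(f"ROI '{self.id}' has an empty mask")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 positive values, got {spacing}")
        self.spacing = spacing

    @property
    def decision(self) -> Optional[int]:
        """Binary decision: 1 = nodule, 0 = non-nodule, None = unknown."""
        if self.label in NODULE_LABELS or self.label == "nodule":
            return 1
        if self.label == "non-nodule":
            return 0
        return None


@dataclass
class RoiSlice:
    """A 2D axial slice of an ROI, used by the 2D feature formulas."""

    intensities: np.ndarray
    mask: np.ndarray
    provenance: Tuple[str, int] = ("", -1)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        mask = np.asarray(self.mask)
        if mask.shape != self.intensities.shape:
            raise ValueError(
                f"mask shape {mask.shape} does not match image shape "
                f"{self.intensities.shape}"
            )
        if self.intensities.ndim != 2:
            raise ValueError("RoiSlice expects 2D arrays (y, x)")
        self.mask = mask != 0


def representative_slice(roi: RoiVolume) -> RoiSlice:
    """Axial slice with maximal foreground area; ties go to the lowest index.

    The 2D descriptors of the feature set need a single slice per ROI; the
    max-area slice is the package's policy and is recorded in provenance.
    """
    counts = roi.mask.sum(axis=(1, 2))
    z = int(np.argmax(counts))  # argmax returns the first maximal index
    return RoiSlice(roi.intensities[z], roi.mask[z], provenance=(roi.id, z))


@dataclass
class FeatureVector:
    """One ROI's ordered 42-slot feature record."""

    values: np.ndarray
    roi_id: str = "roi"
    label: Optional[int] = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (42,):
            raise ValueError(f"expected 42 feature slots, got shape {values.shape}")
        if not np.all(np.isfinite(values)):
            bad = [FEATURE_NAMES[i] for i in np.where(~np.isfinite(values))[0]]
            raise ValueError(f"non-finite feature values in slots {bad}")
        self.values = values

    @property
    def names(self) -> Tuple[str, ...]:
        return FEATURE_NAMES

    def as_dict(self) -> dict:
        return dict(zip(FEATURE_NAMES, self.values))
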