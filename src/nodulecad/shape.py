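"""Shape features fs1-fs18.

Classical 2D descriptors (perimeter, area, circularity, rectangularity,
elongation, Euler number), Hu's seven log-compressed moment invariants, and
three 3D sphericity/compactness descriptors designed for nodule-vs-vessel
discrimination:

* **ESV** (external spherical volume ratio): ROI volume divided by the volume
  of the sphere whose diameter is the ROI's maximum diameter.  1 for a ball,
  small for elongated structures.
* **SCDSTD**: coefficient of variation of the distances from surface voxels
  to the ROI centroid.  0 for a perfect sphere, grows with deviation.
* **ERCLD**: mean distance from the ROI centroid to the 12 edge midpoints of
  its tight bounding box, normalized by the same mean taken from the box
  center.  Exactly 1 when the voxel mass is centered in the box.

All formulas work on lattice coordinates (voxel units); every feature is
translation-invariant by construction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_erosion, generate_binary_structure
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist
from skimage.measure import euler_number as _skimage_euler
from skimage.measure import moments_central, moments_hu, moments_normalized

from .roi import RoiSlice, RoiVolume, representative_slice

_EPS = np.finfo(float).eps


# ---------------------------------------------------------------------------
# 2D descriptors
# ---------------------------------------------------------------------------

def area(slc: RoiSlice) -> int:
    """Foreground pixel count S of the slice."""
    return int(slc.mask.sum())


def perimeter(slc: RoiSlice) -> int:
    """Boundary pixel count C: foreground pixels with a 4-connected
    background (or out-of-grid) neighbor."""
    m = slc.mask
    padded = np.pad(m, 1, constant_values=False)
    interior = (
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    return int((m & ~interior).sum())


def circularity(slc: RoiSlice) -> float:
    """R0 = C^2 / (4*pi*S); larger for more complex/elongated boundaries."""
    s = area(slc)
    if s == 0:
        raise ValueError("circularity requires a nonempty mask")
    return perimeter(slc) ** 2 / (4.0 * np.pi * s)


def _bbox_2d(mask: np.ndarray):
    ys, xs = np.nonzero(mask)
    return ys.min(), ys.max(), xs.min(), xs.max()


def rectangularity(slc: RoiSlice) -> float:
    """S / (H*W) with H, W the bounding-box extent in pixels; in (0, 1]."""
    y0, y1, x0, x1 = _bbox_2d(slc.mask)
    h, w = y1 - y0 + 1, x1 - x0 + 1
    return area(slc) / float(h * w)


def elongation(slc: RoiSlice) -> float:
    """min(H, W) / max(H, W) of the bounding box; in (0, 1]."""
    y0, y1, x0, x1 = _bbox_2d(slc.mask)
    h, w = y1 - y0 + 1, x1 - x0 + 1
    return min(h, w) / float(max(h, w))


def euler_number(slc: RoiSlice) -> int:
    """Components minus holes (8-connected foreground, 4-connected holes)."""
    return int(_skimage_euler(slc.mask, connectivity=2))


# ---------------------------------------------------------------------------
# Hu moment invariants
# ---------------------------------------------------------------------------

@dataclass
class HuMoments:
    """Seven Hu invariants, raw and log10-compressed."""

    raw: np.ndarray
    compressed: np.ndarray


def hu_moments(slc: RoiSlice, gray_weighted: bool = True, signed: bool = False) -> HuMoments:
    """Seven Hu moment invariants of the masked slice, log-compressed.

    Geometric moments use the gray function masked to the ROI; if the masked
    intensity sum is zero (or ``gray_weighted=False``) the binary mask itself
    is the density.  Normalized central moments use the scale exponent
    gamma = (p+q)/2 + 1; invariants are compressed as ``log10(|C_k|)`` with a
    machine-epsilon floor (``signed=True`` switches to
    ``sign(C_k) * log10(1 + |C_k|)``).
    """
    f = slc.intensities * slc.mask if gray_weighted else slc.mask.astype(float)
    if f.sum() <= 0:
        # degenerate gray mass: fall back to binary occupancy
        f = slc.mask.astype(float)
    mu = moments_central(f, order=3)
    nu = moments_normalized(mu, order=3)
    raw = moments_hu(nu)
    if signed:
        compressed = np.sign(raw) * np.log10(1.0 + np.abs(raw))
    else:
        compressed = np.log10(np.maximum(np.abs(raw), _EPS))
    return HuMoments(raw=raw, compressed=compressed)


# ---------------------------------------------------------------------------
# 3D descriptors
# ---------------------------------------------------------------------------

_STRUCT6 = generate_binary_structure(3, 1)


def surface_voxels(mask: np.ndarray) -> np.ndarray:
    """(n, 3) coordinates of foreground voxels with a 6-connected background
    (or out-of-grid) neighbor."""
    interior = binary_erosion(mask, _STRUCT6, border_value=0)
    return np.argwhere(mask & ~interior)


def _feret_diameter(points: np.ndarray) -> float:
    """Maximum pairwise Euclidean distance between points (3D Feret)."""
    if len(points) < 2:
        return 0.0
    pts = points.astype(float)
    if len(pts) > 500:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # degenerate (coplanar/collinear) sets fall through to brute force
    return float(pdist(pts).max())


@dataclass
class BoundingGeometry:
    """Tight axis-aligned bounding box of a mask with derived quantities."""

    mins: np.ndarray          # per-axis min voxel index
    maxs: np.ndarray          # per-axis max voxel index (inclusive)
    edge_midpoints: np.ndarray  # (12, 3) centers of the box edges
    max_diameter: float       # Feret diameter over surface voxels
    centroid: np.ndarray      # foreground voxel centroid


def bounding_geometry(roi: RoiVolume) -> BoundingGeometry:
    coords = np.argwhere(roi.mask)
    mins = coords.min(axis=0).astype(float)
    maxs = coords.max(axis=0).astype(float)
    centroid = coords.mean(axis=0)
    mids = []
    # An edge of the box is parallel to one axis; its midpoint takes the box
    # center on that axis and a (min, max) corner value on the other two.
    for axis in range(3):
        others = [a for a in range(3) if a != axis]
        for lo_hi in itertools.product([0, 1], repeat=2):
            m = np.empty(3)
            m[axis] = (mins[axis] + maxs[axis]) / 2.0
            for o, bit in zip(others, lo_hi):
                m[o] = mins[o] if bit == 0 else maxs[o]
            mids.append(m)
    return BoundingGeometry(
        mins=mins,
        maxs=maxs,
        edge_midpoints=np.asarray(mids),
        max_diameter=_feret_diameter(surface_voxels(roi.mask)),
        centroid=centroid,
    )


def volume(roi: RoiVolume) -> int:
    """Foreground voxel count."""
    return int(roi.mask.sum())


def esv(roi: RoiVolume) -> float:
    """E1: ROI volume over the volume of its circumscribed sphere.

    The sphere diameter is the maximum pairwise distance between surface
    voxel centers.  ~1 for a ball, ~0.37 for a cube, near 0 for rods.
    """
    dim = _feret_diameter(surface_voxels(roi.mask))
    if dim <= 0:
        return 1.0  # single voxel: degenerate, treated as a perfect point-sphere
    vs = (4.0 / 3.0) * np.pi * (dim / 2.0) ** 3
    return volume(roi) / vs


def scdstd(roi: RoiVolume) -> float:
    """E2: std/mean of surface-voxel distances to the ROI centroid.

    0 for a perfect sphere; grows as the surface departs from sphericity.
    """
    surf = surface_voxels(roi.mask)
    centroid = np.argwhere(roi.mask).mean(axis=0)
    d = np.linalg.norm(surf - centroid, axis=1)
    mean = d.mean()
    if mean <= 0:
        return 0.0  # single voxel
    return float(d.std() / mean)


def ercld(roi: RoiVolume) -> float:
    """E3: centroid-to-edge-midpoint mean distance, normalized.

    The numerator is the mean distance from the ROI centroid to the 12 edge
    midpoints of its tight bounding box; the denominator repeats the measure
    from the box center.  The ratio is dimensionless, scale-invariant, and
    exactly 1 for any ROI whose centroid sits at the box center.
    """
    geom = bounding_geometry(roi)
    box_center = (geom.mins + geom.maxs) / 2.0
    denom = np.linalg.norm(geom.edge_midpoints - box_center, axis=1).mean()
    if denom <= 0:
        return 1.0  # degenerate single-voxel box
    num = np.linalg.norm(geom.edge_midpoints - geom.centroid, axis=1).mean()
    return float(num / denom)


def shape_feature_block(roi: RoiVolume) -> np.ndarray:
    """Assemble the 18-slot shape block fs1..fs18 for one ROI.

    fs1 perimeter, fs2 area, fs3 volume, fs4 circularity, fs5 rectangularity,
    fs6 elongation, fs7 Euler number (all but fs3 on the representative
    slice), fs8 ESV, fs9 SCDSTD, fs10 ERCLD, fs11 maximum 3D diameter,
    fs12..fs18 Hu invariants C1..C7 (log-compressed).
    """
    slc = representative_slice(roi)
    hu = hu_moments(slc)
    dim = _feret_diameter(surface_voxels(roi.mask))
    vol = volume(roi)
    e1 = 1.0 if dim <= 0 else vol / ((4.0 / 3.0) * np.pi * (dim / 2.0) ** 3)
    return np.array(
        [
            perimeter(slc),
            area(slc),
            vol,
            circularity(slc),
            rectangularity(slc),
            elongation(slc),
            euler_number(slc),
            e1,
            scdstd(roi),
            ercld(roi),
            dim,
            *hu.compressed,
        ],
        dtype=float,
    )
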